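# Methods

`mcswim` couples a Stokesian-dynamics model of a bilophotrichous coccus — a
spherical cell driven by two sheathed flagellar bundles, one pushing and one
pulling — with the trajectory-analysis pipeline used to characterise the
resulting 3D swim tracks.  This note describes the model, its parameters,
the numerical scheme, the synthetic-data generator, and the design choices
made where the problem was genuinely open.

## Mechanical model

**Body.**  A rigid sphere of radius `Rb = 0.65 µm` with Stokes frictions
`γbt = 6πηRb` and `γbr = 8πηRb³` (water, `η = 1e-3 pN·s/µm²`).

**Flagellar bundles.**  Each bundle is a chain of 20 beads (diameter 50 nm,
bond `ℓ0 = 0.2 µm`, contour 4 µm including the hook segment) with a
discrete elastic-rod energy: harmonic stretching (`ks = 1000 pN`), bending
and twisting (`κb = κt = 7 pN·µm²`) about an intrinsic helical rest shape.
Reference directors are space-parallel-transported from the body anchor
frame, so material twist lives in one angle per bond; the intrinsic shape is
a constant discrete curvature in the material frame plus a constant twist
increment.  Winding the base angle therefore cranks the preferred shape
about the base tangent — this is how motor torque becomes thrust.  Elastic
forces are exact analytic gradients of the energy (reverse-mode
differentiation of the forward construction, validated against central
differences to 1e-10).

**Anchoring.**  The two anchor axes are separated by the opening angle
(default 60°, swept 30–120°), symmetric about the body axis.  The first
bead sits one body radius plus one bond from the centre and is rigid with
the body.  The rest helix is built coaxial with the anchor axis, so the
motor cranks the filament compactly like a balanced corkscrew.  The hook is
a cone clamp: it penalises deviations of the first-bond polar angle from
the rest-helix value (configurable `hook_stiffness`, default
1000 pN·µm/rad²) but is free in azimuth — the motor degree of freedom.
Per-flagellum tilt offsets shift the preferred cone angle.

**Drive.**  Each motor applies a torque (default `Tm = 12 pN·µm`,
3.5× the single-motor reference of 12/3.5 pN·µm) to the base twist angle,
with the exact counter-torque on the body; CCW is defined looking from the
tip toward the body, and CCW paired with the left-handed rest helix makes
a trailing bundle push.  Sense schedules are piecewise constant
(free swimming, transient synchronous rotation, sweeps).

**Hydrodynamics.**  Translational velocities follow from a dense grand
mobility: anisotropic local drag per bead (`γ∥ℓ0`, `γ⊥ℓ0` resolved along
the local tangent), Stokes drag for the body, and Rotne–Prager–Yamakawa
cross-mobilities between all particle pairs (unequal radii for bead–body,
with the overlap-regularised branch).  Rotational cross-coupling is
omitted; bead spin and body rotation use local rotational frictions.  The
assembly is symmetric positive definite on all sampled configurations.
Excluded volume is a WCA (truncated, shifted Lennard-Jones) repulsion
between non-adjacent beads and between beads and the body
(`ε = 1 pN·µm`, `σ` = bead diameter or contact radius).

**Magnetics.**  The magnetosome moment (default `|m| = 2e-16 A·m²`,
configurable) is fixed in the body frame; the default rule places it
perpendicular to the bisector of the two anchor axes, in the flagellar
plane.  Torque `m × B` acts on the body (1 A·m² × 1 mT = 1e15 pN·µm).

## Calibrated parameters

Two constants are not usable as printed and were calibrated once, then
frozen:

- **Bundle spin friction `γr`.**  The per-bead value quoted for a bare
  50-nm filament (~1e-6 pN·µm·s) is dynamically negligible; with it, no
  admissible filament geometry reproduces the observed 100–150 Hz bundle
  rotation, because a local penalty rod caps the torque transmissible from
  material spin into a wide crank at ~`κb·κ̄²·ℓ0` ≈ 2.8 pN·µm per vertex
  (wider helices phase-slip; verified numerically).  `γr` is therefore an
  *effective* spin friction of the sheathed seven-flagella bundle,
  `1.0e-3 pN·µm·s` per bead (≈ `4πη a_eff² ℓ0` with `a_eff ≈ 0.7 µm`),
  calibrated so the default-torque rotation rate lands at ~100 Hz.
- **Filament rest helix.**  Radius 0.2 µm, pitch 2.0 µm, left-handed
  (normal-form-like values); exposed as configuration.

With these defaults the model swims in push–pull mode with bundle rotation
≈ 101 Hz, a fast body-roll wobble (the counter-torque of the two motors
rolls the body about the axis joining the anchors), and a slow large helix
of period ≈ 66 ms.  The model reproduces the qualitative structure of the
observed motility — double-helical tracks only in push–pull mode,
millisecond re-orientations under transient synchronous rotation, slow
field-driven spiralling at 3 mT — but not all printed magnitudes: the
large-helix diameter and the path speed remain well below/above the
published simulated values (see Limitations).

## Numerical scheme

State: body position and quaternion, free-bead positions, one twist angle
per bond.  The equations of motion are integrated by a two-stage
second-order Rosenbrock-W (ROS2, γ = 1+1/√2) step:

- The stiff stretching force is treated linearly-implicitly with its
  bond-direction dyadic Jacobian and the local drag; projecting on bond
  directions reduces each stage solve to a scalar tridiagonal system per
  filament.  The anchored first bead enters as a moving boundary with its
  instantaneous rigid-body rate.
- The twist chain (relaxation time `γr ℓ0/κt` below the step) is solved
  implicitly with the constant twist-Laplacian Jacobian (tridiagonal).
- Everything else — bending, hook, WCA, motor, magnetic torque, the full
  RPY coupling — is explicit in the two stages.

The default step `dt = 7e-8 s` sits inside the stability region of the
explicit bending modes (the printed `1e-7 s` is linearly unstable for the
printed stretch stiffness under any explicit two-stage scheme; verified by
roundoff-growth measurements from exact rest).  Synchronous-rotation
stretches (both bundles same sense) roll the body much faster and
integrate at `dt = 3e-8 s`, as does a 6 ms relaxation window after every
sense switch; this is automatic and deterministic.  Motor torques are
rate-limited (spin-up ramp 2.4e3 pN·µm/s from rest, 10× that on
reversals): the crank load equilibrates over ~1 ms and instantaneous
application overwinds the twist field.  The dense mobility is refreshed
every 1e-5 s (particles move ~1e-5 µm per step, so it is effectively
constant between refreshes).  The observed convergence order of the body
position is ≥ 1.9 once the step resolves the stretch relaxation
(`dt ≲ 4e-9 s`); at production steps the stiff modes show the usual
pre-asymptotic order reduction of W-methods, which does not affect the
(slaved) bond lengths: strain stays below 0.5% in driven runs.

Simulated problem sizes used by the test suite (chosen as desk-scale
defaults): free-swimming runs of 0.15–0.23 s (two to three large-helix
periods after a 20 ms discarded transient), a 2 s continuous
re-orientation train carrying 20 switch replicates (run times varied over
one bundle-rotation period), and a 0.5 s
strong-field run.

## Trajectory analysis

- `fit_helix`: axis from the regression slope (exact over integer periods),
  period from the dominant peak of the complex transverse spectrum in the
  axis frame, then a nonlinear least-squares polish of the explicit helix
  model.  Noiseless recovery is within 0.1%; at 50 nm localisation noise
  within a few percent.
- `fit_double_helix`: least squares on the superposition model
  `x(t) = [r_l cos 2πt/T_l + r_s cos 2πt/T_s, …, p_l t/T_l]`, initialised
  from the two dominant signed-frequency peaks; accepted only if it beats
  the single-helix residual by ≥ 25%, otherwise it falls back with a flag.
- `fit_helix_frenet`: helix descriptors from discrete Frenet curvature and
  torsion of an arclength-resampled path — usable below one turn, where
  spectral estimators fail (used for the strong-field hyper-helix).
- `qc_filter`: duration ≥ 0.4 s, squared net displacement ≥ 10 µm²
  (the simplest per-track reading of the mean-square-displacement rule),
  mean angle between consecutive raw velocity vectors < 60°.
- `detect_reorientations`: sliding helix-axis estimates from mean
  velocities over one wobble period on either side of each instant
  (the period found from the velocity-direction autocorrelation, with ~4 ms
  pre-smoothing so localisation noise is not mistaken for wobble); an
  event is a > 30° axis change completed within ≤ 10 ms; its duration is
  the FWHM of the angular-speed pulse of the direction signal, its centre
  the pulse plateau midpoint, and its angle the separation of the stable
  axes one window plus a 5 ms guard away.  The 30°/10 ms thresholds
  separate helix wobble (axis jitter ≲ 15° at the study parameters) from
  genuine turns.

## Synthetic tracks

The generator emulates the tracking experiments: exact parametric single
and double helices plus seeded isotropic Gaussian localisation noise
(default σ = 50 nm, sub-pixel for the described optics); re-orientation
tracks built by integrating a helical velocity whose frame rotates at
constant rate over each 2.5–5 ms event (position-continuous, phase
-continuous); and seeded populations with the measured spreads (pitch
5.3 ± 1.3 µm, diameter 1.7 ± 0.2 µm, period 46 ± 32 ms truncated at 5 ms
and at the sampling guard of ≥ 6 frames per period, turning angles
94° ± 39° truncated to [0°, 180°]).  Every generator attaches its complete
ground truth to the track metadata, and all analysis round-trip tests
compare against that, never against copied numbers.  What the generator
does not emulate: optics (no point-spread function or interference
patterns), tracking drop-outs, and speed fluctuations within a track; a
passing round trip therefore validates the estimators, not the imaging
chain.

At high frame rates (1640 fps) with 50 nm noise the consecutive-velocity
QC rule correctly rejects most tracks (the per-frame displacement falls to
the noise scale); population fixtures that exercise QC use the 400 fps
tracking rate.

## Known limitations

- The penalty-based local rod caps motor-torque transmission into wide
  crank orbits (see Calibrated parameters).  As a result the simulated
  push–pull tracks have a large-helix diameter of ~0.3 µm and axial speeds
  of ~15 µm/s — the published simulation values (1.4 µm, V_t ≈ 96 µm/s)
  are not reached, although every qualitative contrast (push–pull vs
  double-pusher, angle and torque trends, millisecond turns, hyper-helix)
  is reproduced.  Reaching the printed magnitudes would require rigid
  (constraint-based) frame–bond coupling, a different model class.
- The fast body-roll wobble dominates the instantaneous path speed, so
  V_t comparisons against the published table values run high.
- Re-orientation turning angles are phase-dependent with a broader spread
  than the published ±8° (measured 53° ± 20° over 20 replicates at the
  frozen defaults).
- In strong fields the compliant hook lets the thrust axis relax toward the
  magnetic moment, so the model shows a decaying alignment spiral rather
  than a steady hyper-helix; the published D ≈ 3.9 µm / P ≈ 19.1 µm values
  require a rigidly held angle between moment and thrust.  Moment-magnitude
  sensitivity: |m| = 2e-16 A·m² spirals over seconds (D ~ 9 µm), |m| = 5e-16
  aligns within ~0.3 s (D < 0.2 µm).
- No thermal fluctuations (the dynamics are deterministic), no walls or
  external flows, no chemotaxis-style decision model for when real cells
  reverse.
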