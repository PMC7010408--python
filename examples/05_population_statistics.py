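"""Population statistics: synthetic cohort with the measured spreads.

Generates 20 tracks with pitch ~ N(5.3, 1.3) µm, diameter ~ N(1.7, 0.2) µm,
period ~ N(46, 32) ms (truncated), applies the QC rules, fits every passing
track and prints the aggregate table (mean, SD, n).
"""
from mcswim import PopulationSpec, fit_helix, make_population, qc_filter
from mcswim.report import aggregate_table

# 400 fps matches the 3D-tracking experiments; at much higher frame rates
# the consecutive-velocity QC rule rejects noisy tracks (frame-to-frame
# displacement falls below the localisation noise)
spec = PopulationSpec(n_tracks=20, seed=4, fps=400.0, noise=0.05,
                      duration_range=(0.45, 0.7))
fits = []
for track in make_population(spec):
    if qc_filter(track).passed:
        try:
            fits.append(fit_helix(track))
        except Exception:
            pass
print(aggregate_table(fits).to_string(index=False))
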