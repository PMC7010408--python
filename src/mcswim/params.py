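"""Physical parameters of the two-bundle swimmer model.

Internal unit system: micrometre (length), piconewton (force), second (time).
Viscosity is therefore given in pN·s/µm² (water: 1.0e-3), rigidities in
pN·µm² and torques in pN·µm.  Magnetic fields are stated in mT and magnetic
moments in A·m²; the conversion 1 A·m² × 1 mT = 1e15 pN·µm is applied where a
magnetic torque is evaluated.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

#: conversion factor: torque [pN·µm] = |m|[A·m²] * |B|[mT] * MOMENT_TORQUE_FACTOR
MOMENT_TORQUE_FACTOR = 1.0e15

#: torque of a single E. coli flagellar motor used as reference, pN·µm
ECOLI_MOTOR_TORQUE = 12.0 / 3.5

_SENSES = ("CCW", "CW")
_MOMENT_RULES = ("perpendicular_to_bisector", "parallel_to_bisector")


@dataclass
class ModelParams:
    """All physical constants of the swimmer model.

    Defaults describe an MC-1-like cell: a 1.3 µm spherical body with two
    sheathed flagellar bundles (4 µm contour, 50 nm thick) anchored on one
    hemisphere, driven by 12 pN·µm motors.
    """

    viscosity: float = 1.0e-3          # pN·s/µm²
    body_radius: float = 0.65          # µm
    n_beads: int = 20                  # beads per flagellum (first bead rigid with body)
    bond_length: float = 0.2           # µm
    bead_diameter: float = 0.05        # µm
    gamma_par: float = 1.6e-3          # pN·s/µm², parallel drag per unit length
    gamma_perp: float = 2.8e-3         # pN·s/µm², perpendicular drag per unit length
    gamma_rot: float = 1.0e-3          # pN·µm·s, effective spin friction per
                                       # bead of the sheathed bundle (calibrated
                                       # to the observed 100-150 Hz rotation)
    kappa_bend: float = 7.0            # pN·µm²
    kappa_twist: float = 7.0           # pN·µm²
    k_stretch: float = 1000.0          # pN
    motor_torque: float = 12.0         # pN·µm
    opening_angle: float = 60.0        # degrees between the two anchor axes
    rotation_sense: Tuple[str, str] = ("CCW", "CW")
    torque_ratio: float = 1.0          # Tm2 / Tm1
    length_ratio: float = 1.0          # L2 / L1
    tilt_offsets: Tuple[float, float] = (0.0, 0.0)  # degrees, hook equilibrium offsets
    magnetic_moment: float = 2.0e-16   # A·m²
    moment_rule: str = "perpendicular_to_bisector"
    moment_azimuth: float = 0.0        # degrees about the bisector; 0 = in the flagellar plane
    B_field: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # mT
    dt: float = 7.0e-8                 # s (stability margin of the scheme's
                                       #    explicit bending modes)
    # equilibrium helix of the filament (calibrated within E. coli normal-form bounds)
    helix_radius: float = 0.2          # µm
    helix_pitch: float = 2.0           # µm
    helix_handedness: str = "left"
    hook_stiffness: float | None = 1000.0  # pN·µm/rad² cone-clamp stiffness
                                       # of the basal anchorage; None uses
                                       # kappa_bend/bond_length
    # numerical / auxiliary choices
    wca_epsilon: float = 1.0           # pN·µm
    hydro_coupling: bool = True        # Rotne-Prager cross-mobilities on/off
    mobility_update_interval: float = 1.0e-5  # s; far-field mobility refresh period

    # ---------------- derived quantities ----------------

    @property
    def bead_radius(self) -> float:
        return 0.5 * self.bead_diameter

    @property
    def hook_stiffness_eff(self) -> float:
        if self.hook_stiffness is None:
            return self.kappa_bend / self.bond_length
        return self.hook_stiffness

    @property
    def gamma_body_trans(self) -> float:
        """Stokes translational friction of the body, 6πηRb (pN·s/µm)."""
        return 6.0 * math.pi * self.viscosity * self.body_radius

    @property
    def gamma_body_rot(self) -> float:
        """Stokes rotational friction of the body, 8πηRb³ (pN·µm·s)."""
        return 8.0 * math.pi * self.viscosity * self.body_radius ** 3

    @property
    def n_beads_per_flagellum(self) -> Tuple[int, int]:
        n2 = max(3, round(self.n_beads * self.length_ratio))
        return (self.n_beads, n2)

    @property
    def contour_lengths(self) -> Tuple[float, float]:
        """Filament contour length from the body surface (hook + bonds), µm."""
        n1, n2 = self.n_beads_per_flagellum
        return (n1 * self.bond_length, n2 * self.bond_length)

    @property
    def motor_torques_pair(self) -> Tuple[float, float]:
        return (self.motor_torque, self.motor_torque * self.torque_ratio)

    @property
    def moment_eff(self) -> float:
        """Moment magnitude expressed as torque per field, pN·µm/mT."""
        return self.magnetic_moment * MOMENT_TORQUE_FACTOR

    # ---------------- validation ----------------

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "viscosity": self.viscosity,
            "body_radius": self.body_radius,
            "bond_length": self.bond_length,
            "bead_diameter": self.bead_diameter,
            "gamma_par": self.gamma_par,
            "gamma_perp": self.gamma_perp,
            "gamma_rot": self.gamma_rot,
            "kappa_bend": self.kappa_bend,
            "kappa_twist": self.kappa_twist,
            "k_stretch": self.k_stretch,
            "dt": self.dt,
            "helix_radius": self.helix_radius,
            "helix_pitch": self.helix_pitch,
            "wca_epsilon": self.wca_epsilon,
            "mobility_update_interval": self.mobility_update_interval,
        }
        for name, value in positive.items():
            if not (value > 0.0) or not math.isfinite(value):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.n_beads < 3:
            raise ValueError(f"n_beads must be >= 3, got {self.n_beads}")
        if not (0.0 < self.opening_angle < 180.0):
            raise ValueError(
                f"opening_angle must lie in (0, 180) degrees, got {self.opening_angle}"
            )
        if len(self.rotation_sense) != 2:
            raise ValueError("rotation_sense must have exactly two entries")
        for s in self.rotation_sense:
            if s not in _SENSES:
                raise ValueError(f"rotation sense must be one of {_SENSES}, got {s!r}")
        if self.helix_handedness not in ("left", "right"):
            raise ValueError("helix_handedness must be 'left' or 'right'")
        if self.moment_rule not in _MOMENT_RULES:
            raise ValueError(f"moment_rule must be one of {_MOMENT_RULES}")
        if self.motor_torque < 0.0 or self.torque_ratio < 0.0:
            raise ValueError("motor torque and torque ratio must be non-negative")
        if self.length_ratio <= 0.0:
            raise ValueError("length_ratio must be positive")
        if len(self.tilt_offsets) != 2:
            raise ValueError("tilt_offsets must have exactly two entries")
        if self.hook_stiffness is not None and self.hook_stiffness <= 0:
            raise ValueError("hook_stiffness must be positive")

    # ---------------- flat config I/O ----------------

    def to_config(self, path: str | Path) -> None:
        """Write a flat ``key: value`` YAML config holding every field."""
        data = dataclasses.asdict(self)
        data["rotation_sense"] = list(self.rotation_sense)
        data["tilt_offsets"] = list(self.tilt_offsets)
        data["B_field"] = list(self.B_field)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_config(cls, path: str | Path, **overrides) -> "ModelParams":
        """Read a flat YAML config written by :meth:`to_config`.

        Unknown keys raise ``ValueError``; keyword overrides take precedence.
        """
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("rotation_sense", "tilt_offsets", "B_field"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


def sense_sign(sense: str) -> float:
    """Signed motor rotation: +1 for CCW, -1 for CW.

    The sense is defined looking from the distal flagellum tip toward the
    body.  Paired with a left-handed filament helix, CCW rotation produces
    thrust toward the body (a pusher when the bundle trails the body).
    """
    if sense == "CCW":
        return 1.0
    if sense == "CW":
        return -1.0
    raise ValueError(f"invalid rotation sense {sense!r}")
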