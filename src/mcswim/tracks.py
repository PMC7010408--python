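"""Time-stamped 3D cell tracks and their plain-text interchange format.

A track is a uniformly sampled sequence of positions in µm with times in
seconds.  The interchange format is tab-separated text with a ``t x y z``
header line; ``#`` starts a comment.  Units are fixed by convention (s, µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


class TrackError(ValueError):
    """Malformed track data."""


@dataclass
class Track:
    """A 3D trajectory sampled at a fixed frame rate."""

    times: np.ndarray          # (n,), s
    positions: np.ndarray      # (n, 3), µm
    fps: float
    source: str = "synthetic"  # simulated | synthetic | experimental
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (len(self.times), 3):
            raise TrackError("times must be (n,), positions (n, 3)")
        if len(self.times) < 10:
            raise TrackError("a track needs at least 10 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise TrackError("non-monotonic time")
        # tolerance slightly above 1e-6 so that files written at 9
        # significant digits (absolute time) round-trip at high frame rates
        if np.abs(dt / dt.mean() - 1.0).max() > 3e-5:
            raise TrackError("non-uniform sampling (relative jitter > 3e-5)")
        if not np.all(np.isfinite(self.positions)):
            raise TrackError("non-finite positions")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    def velocities(self) -> np.ndarray:
        """Consecutive-frame velocity vectors, (n-1, 3), µm/s."""
        return np.diff(self.positions, axis=0) * self.fps

    def with_positions(self, positions: np.ndarray, **meta) -> "Track":
        m = dict(self.meta)
        m.update(meta)
        return Track(self.times.copy(), positions, self.fps, self.source, m)


def read_track_file(path) -> Track:
    """Read a ``t x y z`` tab-delimited track file (units s, µm).

    Malformed rows are reported with their line numbers; missing columns,
    non-monotonic time and NaNs raise descriptive errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TrackError(f"{path}: cannot parse track file: {exc}") from exc
    required = ["t", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackError(f"{path}: missing columns {missing} (header must be 't x y z')")
    bad = df.index[df[required].isna().any(axis=1)].tolist()
    if bad:
        lines = [i + 2 for i in bad[:10]]  # +2: header + 1-based
        raise TrackError(f"{path}: NaN/malformed values at lines {lines}")
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise TrackError(f"{path}: non-monotonic time at line {i + 3}")
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    fps = 1.0 / float(np.median(np.diff(t)))
    return Track(t, pos, fps, source="experimental", meta={"path": str(path)})


def write_track_file(track: Track, path) -> None:
    """Write a track in the ``t x y z`` format at 9 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# source: {track.source}; fps: {track.fps:.9g}\n")
        fh.write("t\tx\ty\tz\n")
        for t, p in zip(track.times, track.positions):
            fh.write(f"{t:.9g}\t{p[0]:.9g}\t{p[1]:.9g}\t{p[2]:.9g}\n")
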