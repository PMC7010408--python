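"""Result tables: per-track helix descriptors and aggregates.

The table schema mirrors the conventional presentation of swim-track
parameters: Diameter (µm), Pitch (µm), Period (ms), V_z (µm/s), V_t (µm/s),
with aggregate rows giving mean ± SD and n.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import HelixFit, ReorientationEvent

__all__ = ["fits_table", "aggregate_table", "events_table", "write_table"]

_COLUMNS = ["Diameter (um)", "Pitch (um)", "Period (ms)",
            "V_z (um/s)", "V_t (um/s)"]


def fits_table(fits: Sequence[HelixFit], labels: Optional[Sequence] = None
               ) -> pd.DataFrame:
    """One row of helix descriptors per analysed track."""
    if not fits:
        raise ValueError("need at least one analysed track")
    rows = []
    for k, f in enumerate(fits):
        rows.append({
            "track": labels[k] if labels is not None else k,
            _COLUMNS[0]: f.diameter,
            _COLUMNS[1]: f.pitch,
            _COLUMNS[2]: f.period_ms,
            _COLUMNS[3]: f.v_z,
            _COLUMNS[4]: f.v_t,
        })
    return pd.DataFrame(rows)


def aggregate_table(fits: Sequence[HelixFit]) -> pd.DataFrame:
    """Mean, SD and n over a set of per-track fits (deterministic order)."""
    df = fits_table(fits)
    vals = df[_COLUMNS]
    out = pd.DataFrame({
        "statistic": ["mean", "sd", "n"],
        **{c: [vals[c].mean(), vals[c].std(ddof=1) if len(df) > 1 else 0.0,
               float(len(df))] for c in _COLUMNS},
    })
    return out


def events_table(events: Iterable[ReorientationEvent]) -> pd.DataFrame:
    rows = [{
        "time (s)": e.time,
        "duration (ms)": 1e3 * e.duration,
        "angle (deg)": e.angle,
    } for e in events]
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path) -> None:
    """Tab-separated text with a comment-friendly header."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
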