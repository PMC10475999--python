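"""Collapse gas-exchange time series to per-plant, per-level steady states.

Each record is assigned to a VPD step by elapsed time against the design
schedule (value-matching on RH is ambiguous during transitions).  The
steady-state value at a level is the mean over the final ``window_min``
minutes of that step: the protocol holds each humidity level for 60-90
minutes so the last few minutes are effectively at equilibrium, and a
window mean is far less noise-sensitive than a single snapshot reading.
The realized VPD for the level is the mean leaf-to-air VPD over the same
window.

Levels without records in the window are flagged missing rather than
interpolated; downstream statistics use available levels only.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .envphys import intrinsic_wue
from .ingest import GasExchangeSeries, StepDesign

__all__ = ["extract_steady_state", "steady_state_table", "max_gs"]

#: Columns of the steady-state table.
COLUMNS = ["plant", "accession", "level", "vpd", "gs", "e", "a", "iwue", "missing"]


def extract_steady_state(series: GasExchangeSeries, design: StepDesign,
                         window_min: float = 5.0) -> pd.DataFrame:
    """Steady-state rows (one per design level) for a single plant.

    Raises ``ValueError`` if every level is missing.
    """
    if window_min <= 0:
        raise ValueError("window_min must be positive")
    t = series.data["time_s"].to_numpy(dtype=float)
    edges = design.boundaries_s()
    rows = []
    for step in design.steps:
        t_end = edges[step.index + 1]
        mask = (t >= t_end - window_min * 60.0) & (t <= t_end)
        if not mask.any():
            rows.append(
                dict(plant=series.plant_id, accession=series.accession_id,
                     level=step.index, vpd=np.nan, gs=np.nan, e=np.nan,
                     a=np.nan, iwue=np.nan, missing=True)
            )
            continue
        win = series.data.loc[mask]
        gs = float(win["gs"].mean())
        a = float(win["a"].mean())
        rows.append(
            dict(plant=series.plant_id, accession=series.accession_id,
                 level=step.index, vpd=float(win["vpd_leaf"].mean()),
                 gs=gs, e=float(win["e"].mean()), a=a,
                 iwue=intrinsic_wue(a, gs) if gs > 0 else np.nan,
                 missing=False)
        )
    out = pd.DataFrame(rows, columns=COLUMNS)
    if out["missing"].all():
        raise ValueError(f"plant {series.plant_id}: no level overlaps the series")
    return out


def steady_state_table(collection: Iterable[GasExchangeSeries], design: StepDesign,
                       window_min: float = 5.0) -> pd.DataFrame:
    """Stack :func:`extract_steady_state` over a cohort of plants."""
    frames = [extract_steady_state(s, design, window_min) for s in collection]
    return pd.concat(frames, ignore_index=True)


def max_gs(table: pd.DataFrame) -> pd.Series:
    """Per-plant maximum steady-state gs across levels (missing ignored).

    Raises ``ValueError`` for a plant with no non-missing level.
    """
    ok = table.loc[~table["missing"]]
    out = ok.groupby("plant")["gs"].max()
    empty = set(table["plant"].unique()) - set(out.index)
    if empty:
        raise ValueError(f"no non-missing levels for plant(s) {sorted(empty)}")
    return out
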