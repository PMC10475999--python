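"""Gravimetric whole-plant transpiration from balance logs.

A plant standing on a balance loses mass only through transpiration
(the pot is covered, so soil evaporation is negligible).  The
transpiration rate during a VPD step is the mass difference between the
5-minute average weight at the start and at the end of the step,
normalised by leaf area and elapsed time, and converted from grams of
water to millimoles (molar mass 18.015 g mol^-1):

    E_rate = (m_start - m_end) / (LA * dt) / 18.015 * 1000   [mmol m-2 s-1]

Note the sign: mass decreases while the plant transpires, so the
start-minus-end difference is taken to make transpiration positive.
``dt`` is the time between the two window centres, computed from the
actual record timestamps.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .envphys import MOLAR_MASS_WATER
from .ingest import BalanceSeries, StepDesign
from .leaf_metrics import phi_e

__all__ = ["transpiration_from_weights", "whole_plant_table", "phi_e_whole_plant"]

log = logging.getLogger(__name__)

COLUMNS = ["plant", "accession", "level", "vpd", "e_rate",
           "m_start", "m_end", "dt_s", "missing"]


def transpiration_from_weights(series: BalanceSeries, design: StepDesign,
                               window_min: float = 5.0,
                               negative_tol_g: float = 0.05) -> pd.DataFrame:
    """Per-step whole-plant transpiration rates for one plant.

    Steps without records in both the start and end window are flagged
    missing.  A mass *gain* larger than ``negative_tol_g`` triggers a
    warning (a watering event is the usual culprit) but the rate is
    still reported.
    """
    t = series.data["time_s"].to_numpy(dtype=float)
    m = series.data["mass_g"].to_numpy(dtype=float)
    edges = design.boundaries_s()
    la = series.leaf_area_m2
    w = window_min * 60.0
    rows = []
    for step in design.steps:
        t0, t1 = edges[step.index], edges[step.index + 1]
        start = (t >= t0) & (t <= t0 + w)
        end = (t >= t1 - w) & (t <= t1)
        if not start.any() or not end.any():
            rows.append(dict(plant=series.plant_id, accession=series.accession_id,
                             level=step.index, vpd=step.vpd_value(), e_rate=np.nan,
                             m_start=np.nan, m_end=np.nan, dt_s=np.nan, missing=True))
            continue
        m_start = float(m[start].mean())
        m_end = float(m[end].mean())
        dt = float(t[end].mean() - t[start].mean())
        loss = m_start - m_end
        if loss < -negative_tol_g:
            log.warning("plant %s step %d: mass gained %.3f g (watering event?)",
                        series.plant_id, step.index, -loss)
        e_rate = loss / (la * dt) / MOLAR_MASS_WATER * 1000.0
        rows.append(dict(plant=series.plant_id, accession=series.accession_id,
                         level=step.index, vpd=step.vpd_value(), e_rate=e_rate,
                         m_start=m_start, m_end=m_end, dt_s=dt, missing=False))
    return pd.DataFrame(rows, columns=COLUMNS)


def whole_plant_table(collection: Iterable[BalanceSeries], design: StepDesign,
                      window_min: float = 5.0) -> pd.DataFrame:
    """Stack :func:`transpiration_from_weights` over a cohort."""
    frames = [transpiration_from_weights(s, design, window_min) for s in collection]
    return pd.concat(frames, ignore_index=True)


def phi_e_whole_plant(rates: pd.DataFrame, baseline_levels: Sequence[int] = (0, 1),
                      target_levels: Sequence[int] | None = None) -> pd.DataFrame:
    """Whole-plant transpiration reduction.

    Identical contract to the leaf-level statistic: a two-point line
    through the first two VPD levels, extrapolated to the target level
    (by default the highest level present).
    """
    if target_levels is None:
        target_levels = [int(rates["level"].max())]
    return phi_e(rates, baseline_levels=baseline_levels,
                 target_levels=target_levels, value_col="e_rate")
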