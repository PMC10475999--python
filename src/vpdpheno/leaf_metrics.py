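"""Leaf-level VPD response statistics.

Three statistics summarise how a plant throttles water loss as the
leaf-to-air vapour pressure deficit (VPD) rises:

* transpiration reduction ``phi_E = 1 - E_meas / E_pred``, where E_pred
  extrapolates the straight line through the transpiration rate at the
  two lowest VPD levels out to a higher target level — the fractional
  shortfall of observed transpiration below a purely physical
  (constant-conductance) response;
* limitation of assimilation,
  ``sum(A_max - A_meas) / sum(A_meas)`` over the plants of an accession
  at a fixed level, with A_max each plant's own maximum across levels —
  the photosynthetic cost of stomatal closure;
* stomatal reduction ``phi_stom``: the absolute slope of the
  log-linear decline ``gs = a - phi_stom * ln(VPD_leaf)``, with ``a``
  the fitted gs at 1 kPa.

All three operate on the steady-state table (plant x level rows).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "phi_e",
    "limitation_of_a",
    "stomatal_reduction",
    "fit_stomatal_reduction",
    "accession_means",
]

log = logging.getLogger(__name__)


def _baseline_line(v1, e1, v2, e2):
    if v1 == v2:
        raise ValueError("degenerate baseline: identical VPD at both levels")
    slope = (e2 - e1) / (v2 - v1)
    return slope, e1 - slope * v1


def phi_e(table: pd.DataFrame, baseline_levels: Sequence[int] = (0, 1),
          target_levels: Sequence[int] | None = None,
          value_col: str = "e") -> pd.DataFrame:
    """Transpiration reduction per plant at each target level.

    Fits the exact two-point line through ``value_col`` at the two
    baseline levels (a least-squares line through two points is that
    line), extrapolates to each target level's realized VPD, and
    returns rows (plant, accession, level, vpd, e_pred, e_meas, phi_e,
    valid).  Plants missing a baseline level are excluded with a logged
    reason; targets with non-positive E_pred are flagged invalid.

    ``phi_e`` may be negative (super-linear response); it is at most 1.
    """
    lo, hi = baseline_levels
    if target_levels is None:
        target_levels = [lv for lv in sorted(table["level"].unique()) if lv not in (lo, hi)]
    rows = []
    for plant, grp in table.groupby("plant", sort=True):
        grp = grp.loc[~grp["missing"]].set_index("level")
        if lo not in grp.index or hi not in grp.index:
            log.warning("phi_e: plant %s lacks baseline level(s); excluded", plant)
            continue
        try:
            slope, intercept = _baseline_line(
                grp.at[lo, "vpd"], grp.at[lo, value_col],
                grp.at[hi, "vpd"], grp.at[hi, value_col],
            )
        except ValueError:
            log.warning("phi_e: plant %s has degenerate baseline; excluded", plant)
            continue
        accession = grp["accession"].iloc[0]
        for lv in target_levels:
            if lv not in grp.index:
                continue
            v = grp.at[lv, "vpd"]
            e_meas = grp.at[lv, value_col]
            e_pred = intercept + slope * v
            valid = e_pred > 0
            rows.append(
                dict(plant=plant, accession=accession, level=lv, vpd=v,
                     e_pred=e_pred, e_meas=e_meas,
                     phi_e=(1.0 - e_meas / e_pred) if valid else np.nan,
                     valid=valid)
            )
    return pd.DataFrame(
        rows, columns=["plant", "accession", "level", "vpd", "e_pred",
                       "e_meas", "phi_e", "valid"]
    )


def limitation_of_a(table: pd.DataFrame) -> pd.DataFrame:
    """Accession-level limitation of A at every level.

    A_max is per plant (its maximum steady-state A over levels); the
    sums run over the accession's plants at the fixed level.  The result
    is non-negative and zero only when every plant sits at its maximum.
    Levels where the summed A_meas is non-positive are flagged.
    """
    ok = table.loc[~table["missing"]].copy()
    ok["a_max"] = ok.groupby("plant")["a"].transform("max")
    rows = []
    for (accession, level), grp in ok.groupby(["accession", "level"], sort=True):
        denom = grp["a"].sum()
        num = (grp["a_max"] - grp["a"]).sum()
        if denom <= 0:
            rows.append(dict(accession=accession, level=level,
                             limitation=np.nan, valid=False))
        else:
            rows.append(dict(accession=accession, level=level,
                             limitation=num / denom, valid=True))
    return pd.DataFrame(rows, columns=["accession", "level", "limitation", "valid"])


def fit_stomatal_reduction(vpd_leaf, gs):
    """OLS of gs on ln(VPD_leaf) for one plant.

    Returns ``(a, phi_stom, r2)`` with ``a`` the fitted gs at 1 kPa and
    ``phi_stom`` the absolute slope.  Requires >= 3 levels and non-zero
    variance in ln(VPD).  ``r2`` is NaN for zero-variance gs (the fit is
    then exact but the ratio undefined).
    """
    v = np.asarray(vpd_leaf, dtype=float)
    g = np.asarray(gs, dtype=float)
    if len(v) < 3:
        raise ValueError(f"need >= 3 levels for the stomatal fit, got {len(v)}")
    x = np.log(v)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ln(VPD_leaf)")
    slope, intercept = np.polyfit(x, g, 1)
    resid = g - (intercept + slope * x)
    tss = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else np.nan
    return float(intercept), float(abs(slope)), r2


def stomatal_reduction(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plant stomatal-reduction fits over the steady-state table.

    Plants with fewer than 3 non-missing levels are dropped with a
    logged warning (the single-plant fitter raises instead).
    """
    rows = []
    for plant, grp in table.groupby("plant", sort=True):
        grp = grp.loc[~grp["missing"]]
        if len(grp) < 3:
            log.warning("stomatal_reduction: plant %s has %d level(s) < 3; dropped",
                        plant, len(grp))
            continue
        a, phi_stom, r2 = fit_stomatal_reduction(grp["vpd"], grp["gs"])
        rows.append(dict(plant=plant, accession=grp["accession"].iloc[0],
                         a=a, phi_stom=phi_stom, r2=r2))
    return pd.DataFrame(rows, columns=["plant", "accession", "a", "phi_stom", "r2"])


def accession_means(df: pd.DataFrame, value_col: str,
                    by: Sequence[str] = ("accession",)) -> pd.DataFrame:
    """Mean and standard error of a per-plant statistic per accession.

    Matches the mean +/- se convention used for accession-level figures.
    """
    g = df.groupby(list(by), sort=True)[value_col]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": value_col, "sem": "se", "count": "n"})
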