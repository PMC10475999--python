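"""Segmented (broken-stick) regression of transpiration on VPD.

The transpiration response to rising VPD is modelled as two straight
lines joined continuously at an unknown breakpoint psi:

    y = alpha_plant + b1 * x + b2 * (x - psi)_+ + eps

with a separate intercept per plant (plants of an accession share the
slopes and the breakpoint).  The per-plant intercepts are dummy-coded
fixed offsets: with the 3-8 plants typical of one accession,
variance-component estimation for a random intercept is fragile while
the estimands (psi and the slopes) are unchanged by the fixed-effect
approximation.

Fitting follows the iterative-linearization scheme of Muggeo: at the
current psi the model is linear in the working regressors
U = (x - psi)_+ and V = -1{x > psi}; the coefficient gamma of V
estimates b2 * (psi_true - psi), so psi is updated by gamma/b2 until
the update is below tolerance.  The delta-method standard error of the
breakpoint is SE(gamma)/|b2|.

Whether a breakpoint exists at all is tested with the Davies approach
for a parameter (psi) that is present only under the alternative: the
slope-change Wald statistic is evaluated on a grid of candidate
breakpoints and the maximum is referred to an upper bound for the tail
probability of the supremum of the statistic process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = ["SegmentedFit", "DaviesResult", "fit_segmented", "davies_test",
           "profile_rss"]

_PSI_TOL = 1e-6
_MAX_ITER = 50


# ---------------------------------------------------------------------------
# linear-algebra plumbing


def _dummies(plant_ids):
    plants, inv = np.unique(plant_ids, return_inverse=True)
    d = np.zeros((len(inv), len(plants)))
    d[np.arange(len(inv)), inv] = 1.0
    return plants, d


def _ols(x_mat, y):
    beta, _, rank, _ = np.linalg.lstsq(x_mat, y, rcond=None)
    resid = y - x_mat @ beta
    rss = float(resid @ resid)
    dof = len(y) - rank
    sigma2 = rss / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.pinv(x_mat.T @ x_mat)
    return beta, cov, rss, dof


def _prepare(x, y, plant_ids):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if plant_ids is None:
        plant_ids = np.zeros(len(x), dtype=int)
    plant_ids = np.asarray(plant_ids)
    if len(plant_ids) != len(x):
        raise ValueError("plant_ids must match x in length")
    distinct = np.unique(x)
    if len(distinct) < 4:
        raise ValueError(f"need >= 4 distinct x values, got {len(distinct)}")
    return x, y, plant_ids, distinct


# ---------------------------------------------------------------------------
# segmented fit


@dataclass
class SegmentedFit:
    """Result of a broken-stick fit with per-plant intercepts."""

    psi: float
    psi_se: float
    slope_before: float
    slope_before_se: float
    slope_after: float
    slope_after_se: float
    slope_change: float
    slope_change_se: float
    intercepts: dict = field(default_factory=dict)
    rss: float = np.nan
    sigma2: float = np.nan
    n_obs: int = 0
    n_iter: int = 0
    converged: bool = False
    flags: tuple = ()

    def predict(self, x, plant=None):
        """Fitted mean at ``x`` (continuous at the breakpoint).

        With ``plant=None`` the mean of the per-plant intercepts is used.
        """
        x = np.asarray(x, dtype=float)
        alpha = (np.mean(list(self.intercepts.values()))
                 if plant is None else self.intercepts[plant])
        return (alpha + self.slope_before * x
                + self.slope_change * np.clip(x - self.psi, 0.0, None))


def profile_rss(x, y, plant_ids, psi_values):
    """Residual sum of squares of the broken-stick model at fixed psi.

    The profile objective used for flatness diagnostics; regressors are
    the plant dummies, x and (x - psi)_+.
    """
    x, y, plant_ids, _ = _prepare(x, y, plant_ids)
    _, d = _dummies(plant_ids)
    out = np.empty(len(np.atleast_1d(psi_values)))
    for i, psi in enumerate(np.atleast_1d(psi_values)):
        u = np.clip(x - psi, 0.0, None)
        _, _, rss, _ = _ols(np.column_stack([d, x, u]), y)
        out[i] = rss
    return out if np.ndim(psi_values) else float(out[0])


def _run_iteration(x, y, d, psi, lo, hi, max_iter, tol):
    """One Muggeo run from a starting breakpoint; returns (psi, n_iter, ok).

    The raw gamma/b2 update can overshoot and cycle, so each step is
    backtracked (halved) until the profile RSS does not increase; the
    iteration is then a descent on the profile objective.
    """

    def prof(p):
        u = np.clip(x - p, 0.0, None)
        _, _, rss, _ = _ols(np.column_stack([d, x, u]), y)
        return rss

    cur = prof(psi)
    for it in range(1, max_iter + 1):
        u = np.clip(x - psi, 0.0, None)
        v = -(x > psi).astype(float)
        beta, _, _, _ = _ols(np.column_stack([d, x, u, v]), y)
        beta2, gamma = beta[-2], beta[-1]
        if abs(beta2) < 1e-12:
            # no detectable slope change; psi update undefined
            return psi, it, True
        step = gamma / beta2
        new_psi = float(np.clip(psi + step, lo, hi))
        new_rss = prof(new_psi)
        halvings = 0
        while new_rss > cur + 1e-15 * (1.0 + cur) and halvings < 30:
            step *= 0.5
            new_psi = float(np.clip(psi + step, lo, hi))
            new_rss = prof(new_psi)
            halvings += 1
        if abs(new_psi - psi) < tol:
            return new_psi, it, True
        psi, cur = new_psi, new_rss
    return psi, max_iter, False


def fit_segmented(x, y, plant_ids=None, psi0="auto",
                  max_iter: int = _MAX_ITER, tol: float = _PSI_TOL) -> SegmentedFit:
    """Fit the segmented model, estimating the breakpoint.

    Parameters
    ----------
    x, y : array-like
        Predictor (VPD, kPa) and response (transpiration rate).
    plant_ids : array-like, optional
        Grouping labels giving each plant its own intercept; a single
        common intercept when omitted.
    psi0 : float or "auto"
        Starting breakpoint.  "auto" starts at the median of x and, if
        that run does not converge, restarts from the 25th and 75th
        percentiles; the converged solution with lowest RSS is kept.

    Notes
    -----
    The breakpoint is constrained to the interior of the observed x
    range (a margin of one smallest x-gap at each end); a solution
    pinned at the constraint is flagged ``"boundary"``.  When the
    profile RSS is flat across the interval bracketing the estimate
    (the breakpoint is only interval-identified, e.g. no observations
    between two design levels), the interval midpoint is reported and
    the fit flagged ``"interval-identified"``.
    """
    x, y, plant_ids, distinct = _prepare(x, y, plant_ids)
    plants, d = _dummies(plant_ids)

    gaps = np.diff(distinct)
    delta = float(gaps.min())
    lo, hi = distinct[0] + delta, distinct[-1] - delta
    if lo >= hi:
        span = distinct[-1] - distinct[0]
        lo, hi = distinct[0] + 1e-8 * span, distinct[-1] - 1e-8 * span

    # start at the median (or the supplied psi0) plus the quartiles and
    # the minimiser of a coarse profile scan: the profile RSS can have
    # local minima, and the multi-start sweep with the best-RSS winner
    # is cheap insurance against them
    if psi0 == "auto":
        starts = [float(np.median(x))]
    else:
        starts = [float(psi0)]
    starts += [float(np.quantile(x, q)) for q in (0.25, 0.75)]
    coarse = np.linspace(lo, hi, 25)
    coarse_rss = profile_rss(x, y, plant_ids, coarse)
    starts.append(float(coarse[int(np.argmin(coarse_rss))]))

    runs = [
        _run_iteration(x, y, d, float(np.clip(s, lo, hi)), lo, hi, max_iter, tol)
        for s in starts
    ]

    candidates = [r for r in runs if r[2]] or runs
    scored = [(profile_rss(x, y, plant_ids, psi), psi, it, ok)
              for psi, it, ok in candidates]
    best_rss, psi, n_iter, converged = min(scored, key=lambda t: t[0])

    # the linearized update can stall on a rising branch of the profile
    # (its proposed direction need not be downhill at a kink); a bounded
    # local search around the winner removes that failure mode
    from scipy.optimize import minimize_scalar

    h = (hi - lo) / 24.0
    bracket = (max(lo, psi - h), min(hi, psi + h))
    polish = minimize_scalar(lambda p: profile_rss(x, y, plant_ids, p),
                             bounds=bracket, method="bounded",
                             options={"xatol": 1e-9})
    if polish.fun <= best_rss:
        psi = float(polish.x)

    flags = []
    if not converged:
        flags.append("non-converged")
    if min(abs(psi - lo), abs(psi - hi)) < 10 * tol:
        flags.append("boundary")

    # interval-identification diagnostic: flat profile across the
    # bracketing interval of distinct x values
    j = int(np.searchsorted(distinct, psi, side="right")) - 1
    j = min(max(j, 0), len(distinct) - 2)
    x_lo, x_hi = distinct[j], distinct[j + 1]
    eps = 1e-6 * (x_hi - x_lo)
    probe = np.array([x_lo + eps, 0.5 * (x_lo + x_hi), psi, x_hi - eps])
    probe_rss = profile_rss(x, y, plant_ids, probe)
    if np.ptp(probe_rss) <= 1e-10 * (1.0 + probe_rss.min()):
        psi = float(0.5 * (x_lo + x_hi))
        flags.append("interval-identified")

    # final inference at the estimated breakpoint
    u = np.clip(x - psi, 0.0, None)
    v = -(x > psi).astype(float)
    beta, cov, rss, dof = _ols(np.column_stack([d, x, u, v]), y)
    k = d.shape[1]
    b1, b2 = beta[k], beta[k + 1]
    var_b1, var_b2 = cov[k, k], cov[k + 1, k + 1]
    var_sum = var_b1 + var_b2 + 2.0 * cov[k, k + 1]
    se_gamma = float(np.sqrt(max(cov[-1, -1], 0.0)))

    scale = np.ptp(y) / max(np.ptp(x), 1e-12)
    if abs(b2) < 1e-8 * max(1.0, scale):
        flags.append("no-slope-change")
        psi_se = np.nan
    else:
        psi_se = se_gamma / abs(b2)

    return SegmentedFit(
        psi=float(psi),
        psi_se=float(psi_se),
        slope_before=float(b1),
        slope_before_se=float(np.sqrt(max(var_b1, 0.0))),
        slope_after=float(b1 + b2),
        slope_after_se=float(np.sqrt(max(var_sum, 0.0))),
        slope_change=float(b2),
        slope_change_se=float(np.sqrt(max(var_b2, 0.0))),
        intercepts={p: float(beta[i]) for i, p in enumerate(plants)},
        rss=rss,
        sigma2=float(rss / dof) if dof > 0 else 0.0,
        n_obs=len(y),
        n_iter=n_iter,
        converged=converged,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Davies test


@dataclass
class DaviesResult:
    """Davies-test outcome for 'is there a breakpoint at all?'."""

    p_value: float
    grid: np.ndarray
    statistics: np.ndarray


def davies_test(x, y, plant_ids=None, grid_size: int = 10) -> DaviesResult:
    """Test for a slope change at an unknown breakpoint.

    For ``grid_size`` candidate breakpoints equally spaced between the
    2nd and (n-1)th ordered distinct x, the absolute Wald t statistic
    for the slope-change coefficient (psi held fixed) is computed.  With
    M the maximum over the grid and V the total variation of the
    statistic along it, the p-value is the Davies upper bound for the
    supremum of the statistic process, doubled for the two-sided
    alternative (the slope change may have either sign):

        p = 2 * [Phi(-M) + V * exp(-M^2 / 2) / sqrt(8 * pi)]

    clipped to [0, 1].  A degenerate grid with zero statistic everywhere
    (e.g. exactly linear, noiseless data) yields p = 1.
    """
    x, y, plant_ids, distinct = _prepare(x, y, plant_ids)
    _, d = _dummies(plant_ids)
    if len(distinct) < grid_size + 2:
        grid_size = max(1, len(distinct) - 2)
        warnings.warn(
            f"too few distinct x for the requested grid; using K={grid_size}",
            RuntimeWarning, stacklevel=2,
        )
    grid = np.linspace(distinct[1], distinct[-2], grid_size)

    y_scale = float(y @ y)
    stat = np.empty(grid_size)
    for i, psi in enumerate(grid):
        u = np.clip(x - psi, 0.0, None)
        beta, cov, rss, dof = _ols(np.column_stack([d, x, u]), y)
        b2 = beta[-1]
        se = np.sqrt(max(cov[-1, -1], 0.0))
        if rss <= 1e-12 * max(1.0, y_scale) and abs(b2) < 1e-10:
            stat[i] = 0.0  # exact linear fit: no slope change detectable
        elif se == 0.0 or dof <= 0:
            stat[i] = np.inf if abs(b2) > 0 else 0.0
        else:
            stat[i] = abs(b2) / se

    m = float(np.max(stat))
    if m == 0.0:
        return DaviesResult(p_value=1.0, grid=grid, statistics=stat)
    if not np.isfinite(m):
        return DaviesResult(p_value=0.0, grid=grid, statistics=stat)
    total_variation = float(np.sum(np.abs(np.diff(stat)))) if grid_size > 1 else 0.0
    p = 2.0 * (sstats.norm.sf(m)
               + total_variation * np.exp(-0.5 * m * m) / np.sqrt(8.0 * np.pi))
    return DaviesResult(p_value=float(np.clip(p, 0.0, 1.0)), grid=grid,
                        statistics=stat)
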