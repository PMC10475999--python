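"""Accession-level trait matrix, clustering, ordination and testing.

Each accession is summarised by 16 derived response variables:

* limitation of assimilation at the five upper leaf VPD levels;
* transpiration reduction at the three highest leaf levels and at the
  highest whole-plant level;
* breakpoint, slope before and slope after of the segmented
  transpiration response, at leaf and whole-plant level;
* stomatal reduction (phi_stom).

The matrix of accession means is z-scored per column and partitioned by
k-means over many random centre initialisations (the best within-cluster
sum of squares wins).  The same scaled matrix is projected onto its
principal components for display, with a loadings table ordered by the
absolute first-component loading.  Per-level accession differences are
tested by one-way ANOVA with Benjamini-Hochberg control of the false
discovery rate over the pairwise comparisons at each level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterResult",
    "build_trait_matrix",
    "zscore",
    "kmeans_cluster",
    "pca_project",
    "anova_bh",
    "bh_adjust",
    "correlation_r2",
    "silhouette_by_k",
]

log = logging.getLogger(__name__)


def zscore(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score (sample SD); constant columns are an error."""
    sd = df.std(ddof=1)
    bad = sd[~(sd > 0)].index.tolist()
    if bad:
        raise ValueError(f"constant (zero-variance) trait column(s): {bad}")
    return (df - df.mean()) / sd


def build_trait_matrix(a_limitation: pd.DataFrame,
                       phi_e_leaf: pd.DataFrame,
                       phi_e_wp: pd.DataFrame,
                       seg_leaf: pd.DataFrame,
                       seg_wp: pd.DataFrame,
                       stomatal: pd.DataFrame,
                       a_lim_levels=None,
                       phi_e_levels=None,
                       on_missing: str = "drop") -> pd.DataFrame:
    """Assemble and z-score the accession x 16 trait matrix.

    Parameters
    ----------
    a_limitation, phi_e_leaf, phi_e_wp : DataFrame
        Per-accession-and-level (limitation) or per-plant (phi_e)
        outputs of the leaf / whole-plant metric stages.
    seg_leaf, seg_wp : DataFrame
        One row per accession with columns psi, slope_before,
        slope_after (segmented-fit summaries per measurement level).
    stomatal : DataFrame
        Per-plant stomatal-reduction fits (column phi_stom).
    a_lim_levels, phi_e_levels : sequence of int, optional
        Level indices to use; default all-but-first for the limitation
        and the phi_e target levels present.
    on_missing : "drop" or "impute"
        Accessions lacking any trait are dropped (logged) or
        mean-imputed.

    Returns
    -------
    DataFrame indexed by accession, z-scored per column.
    """
    pieces = {}

    al = a_limitation.loc[a_limitation["valid"]]
    if a_lim_levels is not None:
        al = al[al["level"].isin(a_lim_levels)]
    else:
        a_lim_levels = sorted(al["level"].unique())[1:] if len(al) else []
        al = al[al["level"].isin(a_lim_levels)]
    wide = al.pivot(index="accession", columns="level", values="limitation")
    for lv in wide.columns:
        pieces[f"a_limitation_leaf_L{lv}"] = wide[lv]

    pel = phi_e_leaf.loc[phi_e_leaf["valid"]]
    if phi_e_levels is not None:
        pel = pel[pel["level"].isin(phi_e_levels)]
    mean_pel = pel.groupby(["accession", "level"])["phi_e"].mean().unstack()
    for lv in mean_pel.columns:
        pieces[f"phi_e_leaf_L{lv}"] = mean_pel[lv]

    pw = phi_e_wp.loc[phi_e_wp["valid"]]
    mean_pw = pw.groupby(["accession", "level"])["phi_e"].mean().unstack()
    # single whole-plant target level by construction
    for lv in mean_pw.columns:
        pieces[f"phi_e_wp_L{lv}"] = mean_pw[lv]

    for name, seg in (("leaf", seg_leaf), ("wp", seg_wp)):
        seg = seg.set_index("accession")
        pieces[f"breakpoint_{name}"] = seg["psi"]
        pieces[f"slope_before_{name}"] = seg["slope_before"]
        pieces[f"slope_after_{name}"] = seg["slope_after"]

    pieces["phi_stom"] = stomatal.groupby("accession")["phi_stom"].mean()

    raw = pd.DataFrame(pieces)
    incomplete = raw.index[raw.isna().any(axis=1)].tolist()
    if incomplete:
        if on_missing == "impute":
            log.warning("mean-imputing missing traits for %s", incomplete)
            raw = raw.fillna(raw.mean())
        else:
            log.warning("dropping accession(s) with missing traits: %s", incomplete)
            raw = raw.drop(index=incomplete)
    raw.index.name = "accession"
    return zscore(raw)


@dataclass
class ClusterResult:
    """k-means partition of the scaled trait matrix."""

    k: int
    assignments: pd.Series  # accession -> cluster label in 1..k
    centers: np.ndarray
    inertia: float  # total within-cluster sum of squares
    n_restarts: int
    seed: int | None = None


def kmeans_cluster(scaled: pd.DataFrame, k: int = 3, n_restarts: int = 10000,
                   seed: int | None = 0) -> ClusterResult:
    """Lloyd k-means from ``n_restarts`` random centre sets, best kept.

    Deterministic given ``seed``.  Labels are reported 1-based.
    """
    if k > len(scaled):
        raise ValueError(f"k={k} exceeds the number of accessions ({len(scaled)})")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    km = KMeans(n_clusters=k, init="random", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(scaled.to_numpy())
    return ClusterResult(
        k=k,
        assignments=pd.Series(labels + 1, index=scaled.index, name="cluster"),
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
        n_restarts=n_restarts,
        seed=seed,
    )


def silhouette_by_k(scaled: pd.DataFrame, k_values=(2, 3, 4, 5),
                    n_restarts: int = 100, seed: int | None = 0) -> pd.DataFrame:
    """Mean silhouette width per candidate k (diagnostic only).

    Emitted so the configured k can be inspected; it never auto-selects.
    """
    rows = []
    x = scaled.to_numpy()
    for k in k_values:
        if k >= len(scaled):
            continue
        km = KMeans(n_clusters=k, init="random", n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(x)
        rows.append(dict(k=k, silhouette=float(silhouette_score(x, labels)),
                         inertia=float(km.inertia_)))
    return pd.DataFrame(rows)


def pca_project(scaled: pd.DataFrame):
    """Principal components of the scaled trait matrix.

    Returns ``(scores, loadings, explained_variance_ratio)``.  Loadings
    columns are unit-norm eigenvectors with the sign fixed so each
    component's largest-magnitude entry is positive; the table is sorted
    by \\|PC1 loading\\| descending.  Scores cover all available
    components (rank-limited); the first two are what gets plotted.
    """
    x = scaled.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    ncomp = int(np.sum(s > 1e-12 * (s[0] if len(s) else 1.0)))
    vt = vt[:ncomp]
    # sign convention: largest-|loading| entry of each component positive
    for i in range(ncomp):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    loadings = pd.DataFrame(
        vt.T, index=scaled.columns, columns=[f"PC{i+1}" for i in range(ncomp)]
    )
    scores = pd.DataFrame(
        xc @ vt.T, index=scaled.index, columns=loadings.columns
    )
    var = s[:ncomp] ** 2
    evr = var / np.sum(s**2)
    loadings = loadings.iloc[np.argsort(-np.abs(loadings["PC1"].to_numpy()))]
    return scores, loadings, evr


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def anova_bh(table: pd.DataFrame, value_col: str, group_col: str = "accession",
             level_col: str = "level", min_replicates: int = 2) -> pd.DataFrame:
    """Per-level one-way ANOVA with BH-corrected pairwise comparisons.

    At each VPD level, groups (accessions) with at least
    ``min_replicates`` plants enter an omnibus F-test; all pairwise
    two-sample t-tests at that level are then BH-adjusted as one family
    (matching per-level significance-letter conventions).  Levels with
    fewer than two adequately replicated groups are skipped with a
    warning.

    Returns rows (level, group_a, group_b, f_p, p_raw, p_adj); the
    omnibus p is repeated on each pairwise row of its level.
    """
    rows = []
    data = table
    if "missing" in table.columns:
        data = table.loc[~table["missing"]]
    data = data.dropna(subset=[value_col])
    for level, grp in data.groupby(level_col, sort=True):
        samples = {g: sub[value_col].to_numpy(dtype=float)
                   for g, sub in grp.groupby(group_col)
                   if len(sub) >= min_replicates}
        if len(samples) < 2:
            log.warning("anova_bh: level %s skipped (insufficient replication)", level)
            continue
        names = sorted(samples)
        f_p = float(sstats.f_oneway(*[samples[g] for g in names]).pvalue)
        pairs, raw = [], []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = float(sstats.ttest_ind(samples[names[i]],
                                               samples[names[j]]).pvalue)
                pairs.append((names[i], names[j]))
                raw.append(p)
        adj = bh_adjust(raw)
        for (a, b), pr, pa in zip(pairs, raw, adj):
            rows.append(dict(level=level, group_a=a, group_b=b,
                             f_p=f_p, p_raw=pr, p_adj=float(pa)))
    return pd.DataFrame(rows, columns=["level", "group_a", "group_b",
                                       "f_p", "p_raw", "p_adj"])


def correlation_r2(x, y):
    """Squared Pearson correlation across accessions with two-sided p.

    Requires >= 3 pairs; returns (NaN, NaN) with a warning on zero
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined for zero-variance input",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    r, p = sstats.pearsonr(x, y)
    return float(r * r), float(p)
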