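"""End-to-end orchestration: time series in, phenotype groups out.

``run_pipeline`` chains the stages on in-memory objects and optionally
writes every output table plus one machine-readable JSON summary:

steady-state extraction -> leaf metrics (phi_E, A limitation, phi_stom)
-> whole-plant rates and phi_E -> segmented fits with Davies tests per
accession and measurement level -> trait matrix -> k-means + PCA ->
per-level ANOVA with BH correction -> trait correlations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as ca
from . import leaf_metrics as lm
from . import steady_state as ss
from . import whole_plant as wp
from .ingest import StepDesign, write_table
from .segmented import davies_test, fit_segmented

__all__ = ["PipelineConfig", "run_pipeline", "segmented_by_accession"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    window_min: float = 5.0
    leaf_baseline: tuple = (0, 1)
    leaf_targets: tuple = (3, 4, 5)
    wp_baseline: tuple = (0, 1)
    wp_targets: tuple | None = None  # None -> highest level
    davies_grid: int = 10
    k: int = 3
    n_restarts: int = 10000
    kmeans_seed: int = 0


def segmented_by_accession(table: pd.DataFrame, value_col: str,
                           grid_size: int = 10) -> pd.DataFrame:
    """Fit the segmented model and Davies test per accession.

    ``table`` holds plant x level rows with realized VPD; the response
    is ``value_col`` (leaf E or whole-plant E_rate).
    """
    rows = []
    ok = table.loc[~table["missing"]].dropna(subset=[value_col])
    for acc, grp in ok.groupby("accession", sort=True):
        x = grp["vpd"].to_numpy(dtype=float)
        y = grp[value_col].to_numpy(dtype=float)
        plants = grp["plant"].to_numpy()
        try:
            fit = fit_segmented(x, y, plants)
            dav = davies_test(x, y, plants, grid_size=grid_size)
        except ValueError as exc:
            log.warning("segmented fit skipped for %s: %s", acc, exc)
            continue
        rows.append(dict(
            accession=acc, psi=fit.psi, psi_se=fit.psi_se,
            slope_before=fit.slope_before, slope_before_se=fit.slope_before_se,
            slope_after=fit.slope_after, slope_after_se=fit.slope_after_se,
            davies_p=dav.p_value, rss=fit.rss, n_obs=fit.n_obs,
            converged=fit.converged, flags=";".join(fit.flags),
        ))
    return pd.DataFrame(rows)


def run_pipeline(gas_series, balance_series, leaf_design: StepDesign,
                 chamber_design: StepDesign, cfg: PipelineConfig | None = None,
                 out_dir=None) -> dict:
    """Run every stage; returns a dict of result frames/objects.

    Keys: steady, max_gs, phi_e_leaf, a_limitation, stomatal,
    wp_rates, phi_e_wp, seg_leaf, seg_wp, traits, clusters, pca_scores,
    pca_loadings, explained_variance, anova, correlations, silhouette.
    """
    cfg = cfg or PipelineConfig()

    steady = ss.steady_state_table(gas_series, leaf_design, cfg.window_min)
    maxgs = ss.max_gs(steady)
    pel = lm.phi_e(steady, cfg.leaf_baseline, cfg.leaf_targets)
    alim = lm.limitation_of_a(steady)
    stom = lm.stomatal_reduction(steady)

    rates = wp.whole_plant_table(balance_series, chamber_design, cfg.window_min)
    pwp = wp.phi_e_whole_plant(rates, cfg.wp_baseline,
                               list(cfg.wp_targets) if cfg.wp_targets else None)

    seg_leaf = segmented_by_accession(steady, "e", cfg.davies_grid)
    seg_wp = segmented_by_accession(rates, "e_rate", cfg.davies_grid)

    traits = ca.build_trait_matrix(alim, pel, pwp, seg_leaf, seg_wp, stom)
    clusters = ca.kmeans_cluster(traits, cfg.k, cfg.n_restarts, cfg.kmeans_seed)
    scores, loadings, evr = ca.pca_project(traits)
    sil = ca.silhouette_by_k(traits, seed=cfg.kmeans_seed)

    anova = pd.concat(
        [ca.anova_bh(steady, col).assign(measure=col)
         for col in ("gs", "e", "a", "iwue")],
        ignore_index=True,
    )

    # trait-trait correlations across accessions
    acc_maxgs = maxgs.groupby(
        steady.drop_duplicates("plant").set_index("plant")["accession"]
    ).mean()
    acc_stom = stom.groupby("accession")["phi_stom"].mean()
    common = acc_maxgs.index.intersection(acc_stom.index)
    corr_rows = []
    r2, p = ca.correlation_r2(acc_stom.loc[common], acc_maxgs.loc[common])
    corr_rows.append(dict(x="phi_stom", y="max_gs", r2=r2, p=p, n=len(common)))
    pel_acc = pel.groupby("accession")["phi_e"].mean()
    pwp_acc = pwp.groupby("accession")["phi_e"].mean()
    common = pel_acc.index.intersection(pwp_acc.index)
    if len(common) >= 3:
        r2, p = ca.correlation_r2(pel_acc.loc[common], pwp_acc.loc[common])
        corr_rows.append(dict(x="phi_e_leaf", y="phi_e_wp", r2=r2, p=p,
                              n=len(common)))
    correlations = pd.DataFrame(corr_rows)

    results = dict(
        steady=steady, max_gs=maxgs, phi_e_leaf=pel, a_limitation=alim,
        stomatal=stom, wp_rates=rates, phi_e_wp=pwp, seg_leaf=seg_leaf,
        seg_wp=seg_wp, traits=traits, clusters=clusters, pca_scores=scores,
        pca_loadings=loadings, explained_variance=evr, anova=anova,
        correlations=correlations, silhouette=sil,
    )
    if out_dir is not None:
        write_outputs(results, out_dir, cfg)
    return results


def write_outputs(results: dict, out_dir, cfg: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(results["steady"], out / "steady_state.csv")
    write_table(results["phi_e_leaf"], out / "phi_e_leaf.csv")
    write_table(results["a_limitation"], out / "a_limitation.csv")
    write_table(results["stomatal"], out / "stomatal_reduction.csv")
    write_table(results["wp_rates"], out / "whole_plant_rates.csv")
    write_table(results["phi_e_wp"], out / "phi_e_whole_plant.csv")
    seg = pd.concat(
        [results["seg_leaf"].assign(level="leaf"),
         results["seg_wp"].assign(level="whole-plant")],
        ignore_index=True,
    )
    write_table(seg, out / "segmented_fits.csv")
    write_table(results["traits"].reset_index(), out / "trait_matrix.csv")
    write_table(results["pca_loadings"].reset_index(names="trait"),
                out / "pca_loadings.csv")
    write_table(results["anova"], out / "anova_bh.csv")
    write_table(results["correlations"], out / "correlations.csv")
    write_table(results["silhouette"], out / "silhouette.csv")

    clusters = results["clusters"]
    summary = dict(
        config=asdict(cfg),
        clusters=dict(k=clusters.k, inertia=clusters.inertia,
                      n_restarts=clusters.n_restarts,
                      assignments={str(a): int(c)
                                   for a, c in clusters.assignments.items()}),
        davies=dict(
            leaf={r["accession"]: r["davies_p"]
                  for _, r in results["seg_leaf"].iterrows()},
            whole_plant={r["accession"]: r["davies_p"]
                         for _, r in results["seg_wp"].iterrows()},
        ),
        explained_variance=[float(v) for v in results["explained_variance"]],
    )
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out / "clusters.json", "w", encoding="utf-8") as fh:
        json.dump(summary["clusters"], fh, indent=1, sort_keys=True)
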