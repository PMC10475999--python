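import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from vpdpheno.envphys import MOLAR_MASS_WATER
from vpdpheno.leaf_metrics import phi_e
from vpdpheno.pipeline import PipelineConfig, run_pipeline
from vpdpheno.steady_state import steady_state_table
from vpdpheno.synthetic import (ARCHETYPES, CohortConfig, GroupSpec, NoiseSpec,
                                default_config, generate_cohort,
                                ground_truth_check, true_phi_e, write_cohort)


class TestGeneration:
    def test_same_seed_identical_files(self, tmp_path):
        a = write_cohort(generate_cohort(default_config(seed=9)), tmp_path / "a")
        b = write_cohort(generate_cohort(default_config(seed=9)), tmp_path / "b")
        for key in a:
            assert (tmp_path / "a" / a[key].split("/")[-1]).read_bytes() == \
                   (tmp_path / "b" / b[key].split("/")[-1]).read_bytes()

    def test_adding_a_plant_does_not_perturb_others(self):
        small = generate_cohort(default_config(seed=2, n_plants=2))
        large = generate_cohort(default_config(seed=2, n_plants=3))
        small_map = {s.plant_id: s for s in small.gas_series}
        large_map = {s.plant_id: s for s in large.gas_series}
        for pid, s in small_map.items():
            pd.testing.assert_frame_equal(s.data, large_map[pid].data)

    def test_gs_positive_and_nonincreasing_in_vpd(self, noiseless_cohort):
        tbl = steady_state_table(noiseless_cohort.gas_series,
                                 noiseless_cohort.leaf_design)
        for _, grp in tbl.groupby("plant"):
            gs = grp.sort_values("level")["gs"].to_numpy()
            assert (gs > 0).all()
            assert np.all(np.diff(gs) <= 1e-12)

    def test_negative_steady_e_config_rejected(self):
        bad = (("e0_leaf", -10.0),)
        with pytest.raises(ValueError, match="non-positive steady E"):
            CohortConfig(groups=(GroupSpec("II", 1, 2, bad),))

    def test_intercept_sd_realised(self):
        """Sample SD of plant intercepts across 200 plants is within 3
        standard errors of the configured value."""
        cfg = CohortConfig(groups=(GroupSpec("III", 1, 200),), seed=6)
        cohort = generate_cohort(cfg)
        offs = np.array([
            p["intercept_offset"]
            for p in cohort.truth["accessions"]["III01"]["plants"].values()
        ])
        sd = cfg.noise.intercept_sd
        se_of_sd = sd / np.sqrt(2 * (len(offs) - 1))
        assert abs(offs.std(ddof=1) - sd) < 3 * se_of_sd

    def test_mass_conserved_before_noise(self, noiseless_cohort):
        for s in noiseless_cohort.balance_series:
            m = s.data["mass_g"].to_numpy()
            assert np.all(np.diff(m) <= 1e-12)  # monotone non-increasing
            # total decline is positive and finite
            assert 0.0 < m[0] - m[-1] < m[0]


class TestGroundTruth:
    def test_noiseless_roundtrip_exact(self, noiseless_cohort):
        res = run_pipeline(noiseless_cohort.gas_series,
                           noiseless_cohort.balance_series,
                           noiseless_cohort.leaf_design,
                           noiseless_cohort.chamber_design,
                           PipelineConfig(n_restarts=50))
        assert res["seg_leaf"]["rss"].max() < 1e-12
        rep = ground_truth_check(
            noiseless_cohort.truth,
            {"seg_leaf": res["seg_leaf"], "seg_wp": res["seg_wp"],
             "stomatal": res["stomatal"], "phi_e_leaf": res["phi_e_leaf"],
             "clusters": res["clusters"].assignments},
            tolerances=dict(psi=1e-6, slope=1e-6, psi_wp=1e-6, slope_wp=1e-6,
                            phi_stom=1e-6, phi_e=1e-6),
        )
        assert rep["passed"], [c for c in rep["checks"] if not c["passed"]][:5]

    def test_closed_form_phi_e_matches_pipeline(self, noiseless_cohort):
        tbl = steady_state_table(noiseless_cohort.gas_series,
                                 noiseless_cohort.leaf_design)
        out = phi_e(tbl, (0, 1), [5])
        v_base = noiseless_cohort.truth["leaf_vpds"][:2]
        for _, row in out.iterrows():
            plant = noiseless_cohort.truth["accessions"][row["accession"]][
                "plants"][row["plant"]]
            expected = true_phi_e(plant, row["vpd"], v_base, "leaf")
            assert row["phi_e"] == pytest.approx(float(expected), abs=1e-9)

    def test_noisy_recovery_within_tolerances(self, default_cohort,
                                              default_results):
        rep = ground_truth_check(
            default_cohort.truth,
            {"seg_leaf": default_results["seg_leaf"],
             "seg_wp": default_results["seg_wp"],
             "stomatal": default_results["stomatal"],
             "clusters": default_results["clusters"].assignments},
        )
        assert rep["passed"], [c for c in rep["checks"] if not c["passed"]][:5]

    def test_permuted_cluster_labels_still_pass(self, default_cohort,
                                                default_results):
        labels = default_results["clusters"].assignments
        permuted = labels.map({1: 3, 2: 1, 3: 2})
        rep = ground_truth_check(default_cohort.truth, {"clusters": permuted})
        assert rep["passed"]

    def test_unknown_accession_raises(self, default_cohort, default_results):
        seg = default_results["seg_leaf"].copy()
        seg.loc[0, "accession"] = "nope"
        with pytest.raises(ValueError, match="unknown"):
            ground_truth_check(default_cohort.truth, {"seg_leaf": seg})


def test_archetype_contrasts():
    """Defaults encode the qualitative group contrasts: I breaks early
    with low flux, II turns negative after ~2 kPa, III keeps a high
    breakpoint and a positive second slope."""
    a = ARCHETYPES
    assert a["I"].psi_leaf < a["II"].psi_leaf < a["III"].psi_leaf
    assert a["I"].slope_before_leaf < min(a["II"].slope_before_leaf,
                                          a["III"].slope_before_leaf)
    assert a["II"].slope_after_leaf < 0.0
    assert a["III"].slope_after_leaf > 0.0
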