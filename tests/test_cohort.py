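import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from vpdpheno.cohort import (anova_bh, bh_adjust, build_trait_matrix,
                             correlation_r2, kmeans_cluster, pca_project,
                             zscore)


class TestZscore:
    def test_hand_built_3x2(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [10.0, 10.0, 16.0]})
        z = zscore(df)
        np.testing.assert_allclose(z["x"], [-1.0, 0.0, 1.0])
        sy = np.std([10.0, 10.0, 16.0], ddof=1)
        np.testing.assert_allclose(z["y"], (df["y"] - 12.0) / sy)

    def test_columns_standardised(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(3.0, 2.0, (9, 16)))
        z = zscore(df)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-10)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="constant"):
            zscore(pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]}))


class TestKmeans:
    def planted(self, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0.0] * 4, [10.0] * 4, [-10.0, 10.0, -10.0, 10.0]])
        labels = np.repeat([0, 1, 2], [3, 3, 4])
        x = centers[labels] + rng.normal(0.0, 1.0, (10, 4))
        return pd.DataFrame(x, index=[f"a{i}" for i in range(10)]), labels

    def test_planted_partition_recovered(self):
        df, truth = self.planted()
        res = kmeans_cluster(df, k=3, n_restarts=50, seed=0)
        assert adjusted_rand_score(truth, res.assignments.to_numpy()) == 1.0
        assert set(res.assignments) <= {1, 2, 3}

    def test_n_equals_k_zero_inertia(self):
        df = pd.DataFrame(np.eye(3) * 5.0, index=list("abc"))
        res = kmeans_cluster(df, k=3, n_restarts=10, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_more_restarts_never_worse(self):
        df, _ = self.planted(seed=3)
        few = kmeans_cluster(df, k=3, n_restarts=1, seed=1)
        many = kmeans_cluster(df, k=3, n_restarts=200, seed=1)
        assert many.inertia <= few.inertia + 1e-12

    def test_k_larger_than_n_raises(self):
        df = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError):
            kmeans_cluster(df, k=4)


class TestPca:
    def test_line_explains_all_variance(self):
        t = np.linspace(-1.0, 1.0, 7)
        df = pd.DataFrame({"x": 2.0 * t, "y": -3.0 * t, "z": t})
        _, _, evr = pca_project(df)
        assert evr[0] == pytest.approx(1.0)

    def test_loadings_unit_norm_and_sign_fixed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0.0, 1.0, (9, 5)))
        _, loadings, _ = pca_project(df)
        norms = np.linalg.norm(loadings.to_numpy(), axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)
        for col in loadings.columns:
            v = loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_loadings_sorted_by_abs_pc1(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(0.0, 1.0, (9, 6)))
        _, loadings, _ = pca_project(df)
        pc1 = np.abs(loadings["PC1"].to_numpy())
        assert np.all(np.diff(pc1) <= 1e-12)

    def test_3x2_matches_eigendecomposition_oracle(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 4.0], "y": [0.0, 1.0, 1.0]})
        scores, loadings, evr = pca_project(df)
        xc = df.to_numpy() - df.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(evr, evals / evals.sum(), atol=1e-12)
        v1 = evecs[:, 0] * np.sign(evecs[np.argmax(np.abs(evecs[:, 0])), 0])
        np.testing.assert_allclose(
            loadings["PC1"].reindex(df.columns).to_numpy(), v1, atol=1e-10)

    def test_isometry_with_all_components(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(0.0, 1.0, (8, 5)))
        scores, _, _ = pca_project(df)
        xc = df.to_numpy() - df.to_numpy().mean(axis=0)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(scores.to_numpy()), pdist(xc),
                                   atol=1e-8)


class TestAnovaBh:
    def test_hand_bh(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_bh_monotone_and_never_smaller(self, pvals):
        raw = np.array(pvals)
        adj = bh_adjust(raw)
        assert np.all(adj >= raw - 1e-12)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_null_simulation_large_p(self):
        rng = np.random.default_rng(4)
        rows = []
        for acc in range(4):
            for plant in range(6):
                rows.append(dict(accession=f"a{acc}", plant=f"a{acc}p{plant}",
                                 level=0, value=rng.normal(0.0, 1.0)))
        out = anova_bh(pd.DataFrame(rows), "value")
        assert out["f_p"].iloc[0] > 0.01
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()

    def test_insufficient_replication_skipped(self, caplog):
        df = pd.DataFrame([
            dict(accession="a1", level=0, value=1.0),
            dict(accession="a2", level=0, value=2.0),
        ])
        with caplog.at_level("WARNING"):
            out = anova_bh(df, "value")
        assert out.empty


class TestCorrelationR2:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r2, p = correlation_r2(x, 2.0 * x + 1.0)
        assert r2 == pytest.approx(1.0)

    def test_sign_blind(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = correlation_r2(x, -x)
        assert r2 == pytest.approx(1.0)

    def test_independent_data_small_r2_on_average(self):
        rng = np.random.default_rng(5)
        r2s = [correlation_r2(rng.normal(size=9), rng.normal(size=9))[0]
               for _ in range(200)]
        assert np.mean(r2s) < 0.25

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning):
            r2, p = correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r2)


class TestBuildTraitMatrix:
    def test_default_cohort_yields_16_scaled_traits(self, default_results):
        traits = default_results["traits"]
        assert traits.shape == (9, 16)
        np.testing.assert_allclose(traits.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(traits.std(ddof=1), 1.0, atol=1e-10)

    def test_missing_trait_drops_accession(self, default_results, caplog):
        seg_leaf = default_results["seg_leaf"].iloc[1:]  # drop one accession
        with caplog.at_level("WARNING"):
            traits = build_trait_matrix(
                default_results["a_limitation"], default_results["phi_e_leaf"],
                default_results["phi_e_wp"], seg_leaf,
                default_results["seg_wp"], default_results["stomatal"])
        assert traits.shape[0] == 8


def test_end_to_end_cluster_recovery(default_results, default_cohort):
    """Planted 1/2/6 archetype groups are recovered perfectly (ARI=1)
    by k-means on the trait matrix of the default cohort."""
    truth = [default_cohort.truth["accessions"][a]["archetype"]
             for a in default_results["traits"].index]
    res = kmeans_cluster(default_results["traits"], k=3, n_restarts=200, seed=0)
    assert adjusted_rand_score(truth, res.assignments.to_numpy()) == 1.0
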