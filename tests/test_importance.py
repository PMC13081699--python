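"""Back-projection, permutation nulls, ROI pooling, network enrichment."""

import numpy as np
import pandas as pd
import pytest

from brainage import (
    average_coefficients,
    backproject,
    backproject_predict,
    canonical_edges,
    edge_significance,
    fit_permutation,
    network_representation,
    pool_roi_frequencies,
    predict_raw,
    roi_overrepresentation,
    summarize_edge_classes,
    top_edges_by_sd,
)
from brainage.pipeline import PermutationModel, SplitPlan


def toy_model(components, weights, mean=None, intercept=0.0):
    components = np.asarray(components, dtype=float)
    k, M = components.shape
    return PermutationModel(
        split=SplitPlan(0, np.arange(2), np.empty(0, int), 0),
        pca_mean=np.zeros(M) if mean is None else np.asarray(mean, float),
        pca_components=components,
        explained_variance_ratio=np.full(k, 1.0 / k),
        n_components_retained=k,
        svr_weights=np.asarray(weights, float),
        svr_intercept=float(intercept),
    )


class TestBackprojection:
    def test_identity_components_return_weights(self):
        m = toy_model(np.eye(3), [1.0, -2.0, 0.5])
        assert np.allclose(backproject(m), [1.0, -2.0, 0.5])

    def test_single_component_closed_form(self):
        m = toy_model(np.array([[1, 1]]) / np.sqrt(2), [3.0])
        assert np.allclose(backproject(m), [3 / np.sqrt(2), 3 / np.sqrt(2)])

    def test_equivalence_oracle_on_fitted_models(self, rng):
        """Edge-space predictions equal component-space predictions exactly."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            ages = r.uniform(6, 21, 40)
            X = np.outer(ages, r.normal(0, 0.05, 30)) + r.normal(0, 0.3, (40, 30))
            m = fit_permutation(X, ages)
            X_new = r.normal(0, 1, (15, 30))
            direct = predict_raw(m, X_new)
            via_edges = backproject_predict(m, X_new)
            assert np.allclose(direct, via_edges, rtol=1e-8, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        m = toy_model(np.eye(3), [1.0, 2.0])
        with pytest.raises(ValueError):
            backproject(m)


class TestAverageCoefficients:
    def test_single_model_identity(self):
        m = toy_model(np.eye(2), [2.0, 3.0])
        assert np.allclose(average_coefficients([m]), backproject(m))

    def test_opposite_models_cancel(self):
        a = toy_model(np.eye(2), [1.0, -1.0])
        b = toy_model(np.eye(2), [-1.0, 1.0])
        assert np.allclose(average_coefficients([a, b]), 0.0)

    def test_order_invariant(self, rng):
        ms = [toy_model(np.eye(4), rng.normal(size=4)) for _ in range(3)]
        assert np.allclose(average_coefficients(ms), average_coefficients(ms[::-1]))

    def test_inconsistent_edge_orders_rejected(self):
        a = toy_model(np.eye(2), [1.0, 2.0])
        b = toy_model(np.eye(3), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="inconsistent"):
            average_coefficients([a, b])


class TestEdgeSignificance:
    def test_equal_magnitudes_nothing_significant(self):
        c = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        table = edge_significance(c, n_perm=200, random_state=0)
        assert not table["significant"].any()
        assert (table["p"] == 1.0).all()

    def test_dominant_coefficient_hits_permutation_floor(self):
        rng = np.random.default_rng(1)
        c = rng.normal(0, 0.01, 1000)
        c[137] = 100.0 * np.abs(c).max()
        table = edge_significance(c, n_perm=400, random_state=2)
        assert table.loc[137, "p"] == pytest.approx(1 / 401)
        assert table.loc[137, "abs_rank"] == 1

    def test_flag_rate_matches_alpha_for_exchangeable_coefficients(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=2000)
        table = edge_significance(c, n_perm=500, alpha=0.05, random_state=4)
        rate = table["significant"].mean()
        assert 0.02 <= rate <= 0.08

    def test_pvalues_in_unit_interval_and_monotone_alpha(self):
        rng = np.random.default_rng(5)
        c = rng.normal(size=300)
        t = edge_significance(c, n_perm=200, alpha=0.05, random_state=6)
        assert ((t["p"] > 0) & (t["p"] <= 1)).all()
        flagged_01 = (t["p"] < 0.01).sum()
        assert flagged_01 <= t["significant"].sum()


class TestRoiPooling:
    def test_endpoint_tally(self, toy_parcellation):
        freqs = pool_roi_frequencies(np.array([[0, 1], [0, 2]]), toy_parcellation)
        assert freqs.tolist() == [2, 1, 1, 0]

    def test_frequency_sum_is_twice_edge_count(self, parcellation400, rng):
        edges = canonical_edges(np.arange(400))
        sig = edges[rng.choice(len(edges), 500, replace=False)]
        freqs = pool_roi_frequencies(sig, parcellation400)
        assert freqs.sum() == 1000

    def test_max_roi_share_arithmetic(self):
        """An ROI occurring 150 times among 4000 edges covers 3.75% of them."""
        k, freq = 4000, 150
        assert 100.0 * freq / k == pytest.approx(3.75)


class TestRoiOverrepresentation:
    def test_ubiquitous_roi_at_permutation_floor(self, parcellation400):
        edges = np.array([[0, j] for j in range(1, 201)])
        freqs = pool_roi_frequencies(edges, parcellation400)
        table, _ = roi_overrepresentation(freqs, parcellation400, n_perm=300,
                                          random_state=0)
        assert table.loc[table.roi == 0, "p"].iloc[0] == pytest.approx(1 / 301)

    def test_uniform_frequencies_not_flagged(self, parcellation400):
        freqs = pd.Series(2, index=parcellation400["roi"])  # exactly uniform
        table, _ = roi_overrepresentation(freqs, parcellation400, n_perm=300,
                                          alpha=1e-4, random_state=1)
        assert not table["significant"].any()

    def test_null_draw_conservation(self, parcellation400, rng):
        edges = canonical_edges(np.arange(400))[:50]
        freqs = pool_roi_frequencies(edges, parcellation400)
        _, null = roi_overrepresentation(freqs, parcellation400, n_perm=100,
                                         random_state=2)
        assert (null.sum(axis=1) == 100).all()


class TestNetworkRepresentation:
    def test_single_network_is_trivially_null(self):
        parc = pd.DataFrame({
            "roi": range(6), "name": [f"r{i}" for i in range(6)],
            "network": ["Default"] * 6, "hemisphere": ["L", "R"] * 3,
            "x": np.arange(6.0), "y": np.zeros(6), "z": np.zeros(6),
        })
        freqs = pool_roi_frequencies(np.array([[0, 1], [2, 3]]), parc)
        out = network_representation(freqs, parc, n_perm=100, random_state=0)
        assert len(out) == 1
        assert out["observed_share"].iloc[0] == 1.0
        assert out["p"].iloc[0] == 1.0

    def test_planted_enrichment_flagged(self, parcellation400):
        default_rois = parcellation400.loc[parcellation400.network == "Default",
                                           "roi"].to_numpy()
        edges = np.column_stack([default_rois[:40], default_rois[40:80]])
        freqs = pool_roi_frequencies(edges, parcellation400)
        out = network_representation(freqs, parcellation400, n_perm=500,
                                     random_state=1)
        row = out[out.network == "Default"].iloc[0]
        assert row["direction"] == "over"
        assert row["p"] < 0.01

    def test_shares_sum_to_one(self, parcellation400, rng):
        edges = canonical_edges(np.arange(400))
        sig = edges[rng.choice(len(edges), 200, replace=False)]
        freqs = pool_roi_frequencies(sig, parcellation400)
        out = network_representation(freqs, parcellation400, n_perm=50,
                                     random_state=2)
        assert out["observed_share"].sum() == pytest.approx(1.0)
        assert out["null_mean_share"].sum() == pytest.approx(1.0)


class TestEdgeClassCensus:
    def test_full_set_ratios_are_one(self, parcellation400):
        edges = canonical_edges(np.arange(400))
        census = summarize_edge_classes(edges, edges, parcellation400)
        assert np.allclose(census["rate_ratio"].dropna(), 1.0)

    def test_significant_share_arithmetic(self):
        assert 100.0 * 4000 / 79_800 == pytest.approx(5.01, abs=0.005)

    def test_toy_census_matches_hand_count(self, toy_parcellation):
        edges = canonical_edges(np.arange(4))  # 6 edges
        census = summarize_edge_classes(edges[:2], edges, toy_parcellation)
        # all-edge census by brute force: (0,1)bLL (0,2)wI (0,3)bI (1,2)bI (1,3)wI (2,3)bRR
        full = census.set_index(["network_relation", "hemisphere_relation"])["n_all"]
        assert full[("between", "LL")] == 1
        assert full[("between", "RR")] == 1
        assert full[("between", "inter")] == 2
        assert full[("within", "inter")] == 2
        sig = census.set_index(["network_relation", "hemisphere_relation"])["n_significant"]
        assert sig.sum() == 2
        assert sig[("between", "LL")] == 1 and sig[("within", "inter")] == 1


class TestTopEdgeFilter:
    def test_sd_threshold_filter(self):
        c = np.zeros(100)
        c[7] = 10.0
        mask = top_edges_by_sd(c, n_sd=2.5)
        assert mask[7] and mask.sum() == 1


class TestPlantedEdgeRecovery:
    def test_planted_edges_rank_high(self):
        """Edges carrying the entire age signal dominate |coefficient| ranks."""
        from brainage import BrainAgeEnsemble
        rng = np.random.default_rng(9)
        n, M = 120, 400
        ages = rng.uniform(6, 21, n)
        planted = rng.choice(M, 4, replace=False)
        X = rng.normal(0, 0.10, (n, M))
        for j in planted:
            X[:, j] += 0.05 * ages
        est = BrainAgeEnsemble(n_permutations=10, random_state=0).fit(X, ages)
        coeffs = average_coefficients(est.models_)
        ranks = pd.Series(np.argsort(np.argsort(-np.abs(coeffs))) + 1)
        assert ranks.iloc[planted].mean() <= 0.05 * M
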