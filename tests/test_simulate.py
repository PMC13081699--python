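"""Synthetic cohort, parcellation, and FC generator behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from brainage import (
    SimulationConfig,
    assign_reading_group,
    generate_coordinates,
    generate_parcellation,
    largest_remainder,
    simulate_cohort,
    simulate_dataset,
    simulate_fc,
)
from brainage.simulate import TOWRE_PARAMS


class TestReadingGroupCutoffs:
    @pytest.mark.parametrize("score, group", [
        (90, "PR"), (91, "TR"), (109, "TR"), (110, "ER"),
    ])
    def test_boundaries(self, score, group):
        assert assign_reading_group(score) == group

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            assign_reading_group(float("nan"))


class TestApportionment:
    def test_study_proportions_reproduce_group_sizes(self):
        sizes = largest_remainder(742, (211 / 742, 338 / 742, 193 / 742))
        assert sizes.tolist() == [211, 338, 193]

    @given(st.integers(0, 5000),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_sizes_conserve_total(self, n, weights):
        props = np.asarray(weights) / np.sum(weights)
        assert largest_remainder(n, props).sum() == n


class TestCohort:
    def test_group_sizes_and_composites(self, full_cohort):
        sizes = full_cohort.groupby("group").size()
        assert sizes["ER"] == 193 and sizes["TR"] == 338 and sizes["PR"] == 211
        # every composite obeys its group's cutoff
        assert (full_cohort.loc[full_cohort.group == "PR", "towre_index"] < 91).all()
        tr = full_cohort.loc[full_cohort.group == "TR", "towre_index"]
        assert ((tr >= 91) & (tr <= 109)).all()
        assert (full_cohort.loc[full_cohort.group == "ER", "towre_index"] > 109).all()

    def test_composite_is_mean_of_subtests(self, full_cohort):
        expected = (full_cohort["towre_pde"] + full_cohort["towre_swe"]) / 2
        assert np.allclose(full_cohort["towre_index"], expected)

    def test_ages_within_range(self, full_cohort):
        assert full_cohort["age"].between(6, 21).all()

    def test_determinism(self):
        cfg = SimulationConfig(n_participants=60, seed=42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_small_cohort_respects_cutoffs(self):
        cohort = simulate_cohort(SimulationConfig(n_participants=30, seed=5))
        assert (cohort.loc[cohort.group == "PR", "towre_index"] < 91).all()
        assert (cohort.loc[cohort.group == "ER", "towre_index"] > 109).all()

    def test_mean_composites_match_configured_targets(self):
        """Seed-averaged group composites stay within 1 point of the targets."""
        targets = {g: (TOWRE_PARAMS[g]["pde"][0] + TOWRE_PARAMS[g]["swe"][0]) / 2
                   for g in ("PR", "TR", "ER")}
        means = {g: [] for g in targets}
        for seed in range(50):
            cohort = simulate_cohort(SimulationConfig(n_participants=742, seed=seed))
            for g, m in cohort.groupby("group")["towre_index"].mean().items():
                means[g].append(m)
        for g, target in targets.items():
            # truncation at the cutoff shifts the mean slightly; 1 point covers it
            assert abs(np.mean(means[g]) - target) < 1.0, g


class TestParcellation:
    def test_hemispheres_and_networks(self, parcellation400):
        assert len(parcellation400) == 400
        assert parcellation400["hemisphere"].value_counts().tolist() == [200, 200]
        assert parcellation400["network"].nunique() == 7
        sizes = parcellation400["network"].value_counts()
        assert sizes.idxmax() == "Default"
        assert sizes["Cont"] > sizes["Limbic"]

    def test_small_parcellation_covers_all_networks(self, small_parcellation):
        assert small_parcellation["network"].nunique() == 7

    def test_ids_unique_contiguous(self, parcellation400):
        assert parcellation400["roi"].tolist() == list(range(400))

    def test_centroid_sign_matches_hemisphere(self, parcellation400):
        left = parcellation400[parcellation400.hemisphere == "L"]
        right = parcellation400[parcellation400.hemisphere == "R"]
        assert (left["x"] < 0).all() and (right["x"] > 0).all()

    def test_determinism(self):
        a = generate_parcellation(50, 7, seed=9)
        b = generate_parcellation(50, 7, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_odd_n_roi_rejected(self):
        with pytest.raises(ValueError):
            generate_parcellation(401)


class TestSimulateFC:
    def _noiseless_config(self, **kw):
        base = dict(n_participants=12, n_roi=20, edge_noise_sd=0.0,
                    frac_developmental_edges=0.2, seed=11)
        base.update(kw)
        return SimulationConfig(**base)

    def test_one_year_gap_shifts_developmental_edges_by_slope(self):
        cfg = self._noiseless_config()
        cohort = simulate_cohort(cfg)
        cohort.loc[0, "age"], cohort.loc[1, "age"] = 10.0, 11.0
        parc = generate_parcellation(cfg.n_roi, 7, cfg.seed)
        fc = simulate_fc(cohort, parc, cfg)
        dev = fc.developmental_mask
        diff = fc.X[1] - fc.X[0]
        # exactly one year of the planted slope on every developmental edge
        assert np.allclose(diff[dev], fc.age_slope_z[dev])
        assert np.allclose(np.abs(diff[dev]), cfg.age_slope_z_per_year)
        assert np.allclose(diff[~dev], 0.0)

    def test_lagged_poor_reader_matches_younger_typical_reader(self):
        cfg = self._noiseless_config(maturational_lag_years=1.5,
                                     lag_scope="all_edges")
        cohort = simulate_cohort(cfg)
        pr = cohort.index[cohort.group == "PR"][0]
        tr = cohort.index[cohort.group == "TR"][0]
        cohort.loc[pr, "age"], cohort.loc[tr, "age"] = 10.0, 8.5
        parc = generate_parcellation(cfg.n_roi, 7, cfg.seed)
        fc = simulate_fc(cohort, parc, cfg)
        assert np.allclose(fc.X[pr], fc.X[tr], atol=1e-12)

    def test_no_developmental_edges_means_no_age_signal(self):
        cfg = SimulationConfig(n_participants=500, n_roi=16,
                               frac_developmental_edges=0.0, seed=13)
        cohort = simulate_cohort(cfg)
        parc = generate_parcellation(cfg.n_roi, 7, cfg.seed)
        fc = simulate_fc(cohort, parc, cfg)
        ages = cohort["age"].to_numpy()
        corr = np.array([np.corrcoef(fc.X[:, j], ages)[0, 1]
                         for j in range(fc.X.shape[1])])
        assert np.abs(corr).max() < 0.2
        assert np.abs(corr).mean() < 0.05

    def test_planted_slopes_recovered_by_least_squares(self):
        """With zero noise and no lag, OLS on age recovers every edge slope."""
        cfg = self._noiseless_config(n_participants=40)
        cohort = simulate_cohort(cfg)
        parc = generate_parcellation(cfg.n_roi, 7, cfg.seed)
        fc = simulate_fc(cohort, parc, cfg)
        ages = cohort["age"].to_numpy()
        A = np.column_stack([ages - ages.mean(), np.ones_like(ages)])
        slopes = np.linalg.lstsq(A, fc.X, rcond=None)[0][0]
        assert np.allclose(slopes, fc.age_slope_z, atol=1e-10)

    def test_within_network_baseline_higher(self):
        cfg = self._noiseless_config(n_participants=6)
        cohort = simulate_cohort(cfg)
        parc = generate_parcellation(cfg.n_roi, 7, cfg.seed)
        fc = simulate_fc(cohort, parc, cfg)
        net = parc.set_index("roi")["network"]
        within = (net.loc[fc.edges[:, 0]].to_numpy()
                  == net.loc[fc.edges[:, 1]].to_numpy())
        assert fc.baseline_z[within].mean() > fc.baseline_z[~within].mean() + 0.1

    def test_lag_without_reading_set_rejected(self):
        cfg = self._noiseless_config(maturational_lag_years=1.0)
        cohort = simulate_cohort(cfg)
        parc = generate_parcellation(cfg.n_roi, 7, cfg.seed)
        with pytest.raises(ValueError, match="reading_rois"):
            simulate_fc(cohort, parc, cfg)


class TestCoordinatesAndDataset:
    def test_coordinate_totals(self, parcellation400):
        coords = generate_coordinates(parcellation400, 416, 49, seed=1)
        assert len(coords) == 416

    def test_dataset_roi_ladder_nested(self):
        cfg = SimulationConfig(n_participants=12, n_roi=60, seed=2)
        _, _, _, roi_sets = simulate_dataset(cfg)
        assert len(roi_sets[0]) == 60
        assert set(roi_sets[4]) <= set(roi_sets[2]) <= set(roi_sets[1]) <= set(roi_sets[0])
        assert len(roi_sets[4]) >= 5  # the ladder is nondegenerate
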