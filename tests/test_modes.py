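import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cortexmodes import (
    ResponseRecord,
    DissimilarityMatrix,
    StimulusRegime,
    run_experiment_battery,
    response_dissimilarity,
    dissimilarity_matrix,
    hierarchical_modes,
    clustering_significance,
    mode_exclusivity,
)
from cortexmodes.modes import _derive_seed, simulate_response


def _noise_records(e=8, c=4, t=60, seed=0):
    rng = np.random.default_rng(seed)
    return [ResponseRecord(i, "noise", rng.normal(size=(c, t)), 0.5)
            for i in range(e)]


class TestResponseDissimilarity:
    def test_self_distance_is_zero(self):
        r = _noise_records(1)[0]
        assert response_dissimilarity(r, r, max_lag=5) == pytest.approx(0.0, abs=1e-12)

    def test_time_shift_within_lag_window_is_distance_zero(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(3, 80))
        shift = 4
        r1 = ResponseRecord(0, "a", base, 0.5)
        r2 = ResponseRecord(1, "a", np.roll(base, shift, axis=1), 0.5)
        # rolled edges differ, but the overlap window at the right lag matches
        assert response_dissimilarity(r1, r2, max_lag=shift) == pytest.approx(0.0, abs=1e-9)

    def test_independent_noise_is_near_one(self):
        rng = np.random.default_rng(1)
        n = 4000
        r1 = ResponseRecord(0, "x", rng.normal(size=(1, n)), 0.5)
        r2 = ResponseRecord(1, "y", rng.normal(size=(1, n)), 0.5)
        d = response_dissimilarity(r1, r2, max_lag=3)
        # max over 7 lags of ~N(0, 1/sqrt(n)) correlations
        assert abs(d - 1.0) < 4.0 / np.sqrt(n) + 2.0 / np.sqrt(n)

    def test_symmetry(self):
        a, b = _noise_records(2, seed=7)
        d_ab = response_dissimilarity(a, b, max_lag=6)
        d_ba = response_dissimilarity(b, a, max_lag=6)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)

    def test_lag_monotonicity(self):
        a, b = _noise_records(2, seed=9)
        ds = [response_dissimilarity(a, b, max_lag=l) for l in (0, 2, 5, 10)]
        assert all(x >= y - 1e-12 for x, y in zip(ds, ds[1:]))

    def test_shape_mismatch_rejected(self):
        a = ResponseRecord(0, "a", np.zeros((2, 10)), 0.5)
        b = ResponseRecord(1, "b", np.zeros((3, 10)), 0.5)
        with pytest.raises(ValueError):
            response_dissimilarity(a, b)

    def test_constant_vs_varying_is_distance_one(self):
        a = ResponseRecord(0, "a", np.ones((1, 30)), 0.5)
        b = ResponseRecord(1, "b", np.sin(np.arange(30))[None, :], 0.5)
        assert response_dissimilarity(a, b, max_lag=2) == pytest.approx(1.0)

    def test_identical_constants_are_distance_zero(self):
        a = ResponseRecord(0, "a", np.full((1, 30), 2.0), 0.5)
        b = ResponseRecord(1, "b", np.full((1, 30), 2.0), 0.5)
        assert response_dissimilarity(a, b, max_lag=2) == pytest.approx(0.0)


class TestDissimilarityMatrix:
    def test_matches_pairwise_operation(self):
        recs = _noise_records(6, seed=2)
        d = dissimilarity_matrix(recs, max_lag=5)
        for i in range(6):
            for j in range(6):
                expect = response_dissimilarity(recs[i], recs[j], max_lag=5)
                assert d.values[i, j] == pytest.approx(expect, abs=1e-10)

    def test_permutation_equivariance(self):
        recs = _noise_records(5, seed=4)
        d = dissimilarity_matrix(recs, max_lag=4).values
        perm = [3, 0, 4, 1, 2]
        dp = dissimilarity_matrix([recs[i] for i in perm], max_lag=4).values
        assert np.allclose(dp, d[np.ix_(perm, perm)], atol=1e-12)

    def test_duplicate_record_is_distance_zero(self):
        recs = _noise_records(3, seed=5)
        recs.append(ResponseRecord(9, "dup", recs[0].matrix.copy(), 0.5))
        d = dissimilarity_matrix(recs, max_lag=3)
        assert d.values[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError):
            dissimilarity_matrix(_noise_records(1))


class TestHierarchy:
    @staticmethod
    def _planted(sizes=(4, 4, 4), within=0.1, between=0.9, seed=0):
        e = sum(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        rng = np.random.default_rng(seed)
        d = np.where(labels[:, None] == labels[None, :], within, between)
        d = d + rng.uniform(0, 0.01, (e, e))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        return DissimilarityMatrix(values=d, max_lag=0), labels

    def test_two_records_single_merge(self):
        d = DissimilarityMatrix(values=np.array([[0.0, 1.0], [1.0, 0.0]]), max_lag=0)
        h = hierarchical_modes(d, levels=[2])
        assert sorted(h.assignments[2].tolist()) == [1, 2]

    def test_planted_blocks_recovered_exactly(self):
        d, truth = self._planted()
        h = hierarchical_modes(d, levels=[3])
        assert adjusted_rand_score(truth, h.assignments[3]) == 1.0

    def test_coarser_levels_are_unions_of_finer_clusters(self):
        d, _ = self._planted(sizes=(3, 3, 3, 3), seed=1)
        h = hierarchical_modes(d, levels=[2, 3, 4, 6])
        levels = sorted(h.assignments)
        for coarse, fine in zip(levels, levels[1:]):
            fine_lab = h.assignments[fine]
            coarse_lab = h.assignments[coarse]
            for f in np.unique(fine_lab):
                parents = np.unique(coarse_lab[fine_lab == f])
                assert len(parents) == 1

    def test_medoid_minimises_within_cluster_dissimilarity(self):
        d, truth = self._planted(seed=3)
        h = hierarchical_modes(d, levels=[3])
        for cl, medoid in h.medoids[3].items():
            members = np.nonzero(h.assignments[3] == cl)[0]
            sums = d.values[np.ix_(members, members)].sum(axis=1)
            assert d.values[np.ix_([medoid], members)].sum() == pytest.approx(sums.min())

    def test_level_above_record_count_rejected(self):
        d, _ = self._planted()
        with pytest.raises(ValueError):
            hierarchical_modes(d, levels=[99])


class TestSignificance:
    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            clustering_significance(_noise_records(), n_perm=0)

    def test_separated_modes_reach_minimum_p(self):
        # high-SNR planted modes: each family shares one random waveform,
        # which the circular-shift surrogates destroy
        rng = np.random.default_rng(0)
        families = [rng.normal(size=(3, 100)) for _ in range(3)]
        recs = []
        for i in range(12):
            mat = families[i // 4] + rng.normal(0, 0.05, (3, 100))
            recs.append(ResponseRecord(i, f"fam{i // 4}", mat, 0.5))
        sig = clustering_significance(recs, n_perm=99, seed=1, n_clusters=3)
        assert sig.p_value == pytest.approx(1 / 100)

    def test_p_value_invariant_bounds(self):
        recs = _noise_records(6, seed=8)
        sig = clustering_significance(recs, n_perm=19, seed=2, n_clusters=2)
        assert 0 < sig.p_value <= 1
        assert sig.null_values.shape == (19,)


class TestExclusivity:
    def test_degenerate_distribution_is_fully_exclusive(self):
        act = np.zeros((5, 3))
        act[:, 1] = 1.0
        assert mode_exclusivity(act) == pytest.approx(1.0)

    def test_uniform_co_activation_is_zero(self):
        act = np.full((7, 4), 0.25)
        assert mode_exclusivity(act) == pytest.approx(0.0)

    def test_half_degenerate_half_uniform_is_half(self):
        act = np.vstack([
            np.tile([1.0, 0, 0, 0], (4, 1)),
            np.full((4, 4), 0.25),
        ])
        assert mode_exclusivity(act) == pytest.approx(0.5)

    def test_single_mode_rejected(self):
        with pytest.raises(ValueError):
            mode_exclusivity(np.ones((3, 1)))


class TestBattery:
    def test_labels_and_counts(self, suite):
        records = run_experiment_battery(
            suite.clock_grid, suite.clock_regimes, reps=2, t_end=30.0,
            observed=None, seed=5,
        )
        assert len(records) == 6
        labels = [r.regime_label for r in records]
        assert labels.count("regime-0") == 2

    def test_same_master_seed_replays_identically(self, suite):
        kw = dict(reps=2, t_end=30.0, observed=None, seed=5)
        a = run_experiment_battery(suite.clock_grid, suite.clock_regimes, **kw)
        b = run_experiment_battery(suite.clock_grid, suite.clock_regimes, **kw)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.matrix, rb.matrix)

    def test_single_record_equals_direct_simulation(self, suite):
        records = run_experiment_battery(
            suite.clock_grid, suite.clock_regimes[:1], reps=1, t_end=30.0,
            observed=None, seed=5,
        )
        direct = simulate_response(
            suite.clock_grid, suite.clock_regimes[0], 30.0, None,
            _derive_seed(5, 0, 0),
        )
        assert np.array_equal(records[0].matrix, direct)

    def test_empty_regime_list_rejected(self, suite):
        with pytest.raises(ValueError):
            run_experiment_battery(suite.clock_grid, [], reps=1, t_end=10.0,
                                   observed=None, seed=0)

    def test_three_regime_battery_recovers_modes(self, suite):
        records = run_experiment_battery(
            suite.clock_grid, suite.clock_regimes, reps=4,
            t_end=suite.battery_t_end, observed=None, seed=11,
            t_start=suite.battery_t_start,
        )
        d = dissimilarity_matrix(records, max_lag=8)
        h = hierarchical_modes(d, levels=[3])
        truth = [r.regime_label for r in records]
        assert adjusted_rand_score(truth, h.assignments[3]) >= 0.9
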