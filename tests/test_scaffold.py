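"""Map-level composite statistics, permutation nulls, FDR, model comparison."""

import numpy as np
import pytest
from scipy import stats

from palace.scaffold import (
    PairTables,
    fdr_threshold,
    fisher_average_map,
    map_contrast,
    partial_correlation_map,
    participant_specific_delta,
    two_sided_permutation_p,
)

R_CLIP_MAX = np.arctanh(1 - 1e-7)


def make_tables(rng, S=3, P=4, R=23, effect=0.0, covariates=False, nan_frac=0.0):
    """Synthetic pair tables: scores = effect * rel + noise (room-aligned)."""
    rel = rng.normal(0, 1, (S, P, R))
    scores = np.empty((P, 2, R))
    for p in range(P):
        for t in range(2):
            scores[p, t] = effect * rel[0, p] + rng.normal(0, 1, R)
    if nan_frac:
        mask = rng.uniform(size=scores.shape) < nan_frac
        scores[mask] = np.nan
    cov = rng.normal(0, 1, (P, 2, R, 2)) if covariates else None
    return PairTables(rel=rel, scores=scores, covariates=cov)


class TestFdrThreshold:
    def test_worked_example(self):
        q, sig = fdr_threshold([0.001, 0.01, 0.02, 0.04, 0.9], 0.05)
        assert sig.tolist() == [True, True, True, True, False]

    def test_all_ones_none(self):
        _, sig = fdr_threshold(np.ones(10), 0.05)
        assert not sig.any()

    def test_all_zeros_all(self):
        _, sig = fdr_threshold(np.zeros(10), 0.05)
        assert sig.all()

    def test_nan_excluded(self):
        q, sig = fdr_threshold([0.001, np.nan, 0.9], 0.05)
        assert np.isnan(q[1]) and not sig[1] and sig[0]

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce_bh(self, trial):
        rng = np.random.default_rng(trial)
        p = rng.uniform(0, 1, int(rng.integers(3, 40)))
        alpha = 0.05
        q, sig = fdr_threshold(p, alpha)
        # independent step-up: largest k with p_(k) <= alpha * k / m
        order = np.argsort(p)
        m = len(p)
        k_max = 0
        for k, idx in enumerate(order, start=1):
            if p[idx] <= alpha * k / m:
                k_max = k
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_max]] = True
        assert np.array_equal(sig, expected)
        # q-values: step-up adjusted, monotone
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        assert np.allclose(q[order], np.minimum(adj, 1.0), atol=1e-12)


class TestPermutationP:
    def test_add_one_correction(self):
        p = two_sided_permutation_p(np.array([10.0]), np.zeros((1, 99)))
        assert p[0] == pytest.approx(1 / 100)

    def test_two_sidedness(self):
        null = np.linspace(-1, 1, 200)[None, :]
        p_pos = two_sided_permutation_p(np.array([0.5]), null)
        p_neg = two_sided_permutation_p(np.array([-0.5]), null)
        assert p_pos == pytest.approx(p_neg)


class TestFisherAverageMap:
    def test_perfect_linear_relation_hits_clip(self, rng):
        tables = make_tables(rng, S=1, effect=1.0)
        tables.scores = np.stack(
            [np.stack([2.0 * tables.rel[0, p] + 1.0 for _ in range(2)])
             for p in range(4)]
        )
        res = fisher_average_map(tables, n_perm=100, seed=0)
        assert res.stat[0] == pytest.approx(R_CLIP_MAX)

    def test_toy_matches_pearson_atanh_oracle(self, rng):
        S, P, R = 1, 3, 5
        rel = np.tile(np.array([0.1, 0.4, 0.2, 0.8, 0.5]), (S, P, 1))
        scores = np.tile(np.array([1.0, 2.0, 1.5, 3.0, 2.2]), (P, 2, 1))
        tables = PairTables(rel=rel, scores=scores)
        res = fisher_average_map(tables, n_perm=100, seed=0)
        r_oracle = stats.pearsonr(rel[0, 0], scores[0, 0]).statistic
        assert res.stat[0] == pytest.approx(np.arctanh(r_oracle), abs=1e-10)

    def test_null_composite_near_zero(self, rng):
        tables = make_tables(rng, S=20, P=25, effect=0.0)
        res = fisher_average_map(tables, n_perm=100, seed=1)
        se = 1 / np.sqrt(22) / np.sqrt(25)  # fisher-z SE averaged over cells
        assert abs(res.stat.mean()) < 2 * se

    def test_invariant_to_participant_and_task_order(self, rng):
        tables = make_tables(rng, S=4, P=5, effect=0.3)
        res = fisher_average_map(tables, n_perm=50, seed=2)
        flipped = PairTables(
            rel=tables.rel[:, ::-1].copy(),
            scores=tables.scores[::-1, ::-1].copy(),
        )
        res2 = fisher_average_map(flipped, n_perm=50, seed=2)
        assert np.allclose(res.stat, res2.stat, atol=1e-12)

    def test_constant_scores_excluded_with_warning(self, rng):
        tables = make_tables(rng, S=2, P=3)
        tables.scores[0] = 0.5  # constant for participant 0, both tasks
        res = fisher_average_map(tables, n_perm=50, seed=0)
        assert np.isfinite(res.stat).all()  # other participants carry the map

    def test_requires_three_participants(self, rng):
        with pytest.raises(ValueError):
            fisher_average_map(make_tables(rng, P=2), n_perm=50, seed=0)

    def test_type_one_error_calibrated(self, rng):
        # permutation p-values are valid under the null generator
        pvals = []
        for i in range(30):
            tables = make_tables(np.random.default_rng(i), S=5, P=6,
                                 effect=0.0, nan_frac=0.15)
            res = fisher_average_map(tables, n_perm=99, seed=100 + i)
            pvals.extend(res.p.tolist())
        pvals = np.asarray(pvals)
        for alpha in (0.01, 0.05, 0.1):
            rate = np.mean(pvals <= alpha)
            se = np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert rate <= alpha + 3 * se


class TestPartialCorrelation:
    def test_constant_zero_covariates_equal_raw(self, rng):
        tables = make_tables(rng, S=4, P=5, effect=0.4, covariates=True)
        tables.covariates[:] = 0.0
        raw = fisher_average_map(tables, n_perm=80, seed=3)
        part = partial_correlation_map(tables, n_perm=80, seed=3)
        assert np.allclose(part.stat, raw.stat, atol=1e-10)
        assert np.allclose(part.null, raw.null, atol=1e-10)

    def test_exactly_orthogonal_covariates_no_op(self, rng):
        S, P, R = 2, 4, 12
        rel = rng.normal(0, 1, (S, P, R))
        scores = np.stack(
            [np.stack([0.5 * rel[0, p] + rng.normal(0, 0.5, R)
                       for _ in range(2)]) for p in range(P)]
        )
        cov = np.empty((P, 2, R, 2))
        for p in range(P):
            for t in range(2):
                basis = np.column_stack(
                    [np.ones(R), scores[p, t], *rel[:, p]]
                )
                q, _ = np.linalg.qr(
                    np.column_stack([basis, rng.normal(0, 1, (R, 2))])
                )
                cov[p, t] = q[:, -2:]  # orthogonal to scores, rel, intercept
        tables = PairTables(rel=rel, scores=scores, covariates=cov)
        raw = fisher_average_map(tables, n_perm=60, seed=4)
        part = partial_correlation_map(tables, n_perm=60, seed=4)
        assert np.allclose(part.stat, raw.stat, atol=1e-10)

    def test_missing_covariates_rejected(self, rng):
        with pytest.raises(ValueError, match="covariates"):
            partial_correlation_map(make_tables(rng), n_perm=50, seed=0)


class TestMapContrast:
    def test_identical_maps_nothing_significant(self, rng):
        tables = make_tables(rng, S=5, P=4, effect=0.3, covariates=True)
        tables.covariates[:] = 0.0
        raw = fisher_average_map(tables, n_perm=80, seed=5)
        part = partial_correlation_map(tables, n_perm=80, seed=5)
        res = map_contrast(raw, part)
        assert np.allclose(res.stat, 0.0, atol=1e-10)
        assert not res.sig.any()

    def test_unpaired_permutations_rejected(self, rng):
        tables = make_tables(rng, S=2, P=4, covariates=True)
        raw = fisher_average_map(tables, n_perm=50, seed=0)
        part = partial_correlation_map(tables, n_perm=60, seed=0)
        with pytest.raises(ValueError, match="pair"):
            map_contrast(raw, part)


class TestParticipantSpecificDelta:
    def test_shared_reliability_zero_delta(self, rng):
        S, P, R = 2, 5, 23
        shared = rng.normal(0, 1, (S, 1, R))
        rel = np.broadcast_to(shared, (S, P, R)).copy()
        scores = np.stack(
            [np.stack([0.7 * rel[0, 0] + rng.normal(0, 0.2, R)
                       for _ in range(2)]) for _ in range(P)]
        )
        res = participant_specific_delta(
            PairTables(rel=rel, scores=scores), n_perm=60, seed=0
        )
        assert np.allclose(res.delta, 0.0, atol=1e-12)

    def test_idiosyncratic_reliability_positive_delta(self, rng):
        S, P, R = 2, 6, 23
        rel = rng.normal(0, 1, (S, P, R))
        scores = np.stack(
            [np.stack([0.9 * rel[0, p] + rng.normal(0, 0.3, R)
                       for _ in range(2)]) for p in range(P)]
        )
        res = participant_specific_delta(
            PairTables(rel=rel, scores=scores), n_perm=150, seed=1
        )
        assert res.delta[0] > 0
        assert res.sig[0]

    def test_exact_linear_own_model_r2_one(self, rng):
        S, P, R = 1, 3, 10
        rel = rng.normal(0, 1, (S, P, R))
        scores = np.stack(
            [np.stack([2.0 * rel[0, p] for _ in range(2)]) for p in range(P)]
        )
        res = participant_specific_delta(
            PairTables(rel=rel, scores=scores), n_perm=60, seed=2
        )
        # own R^2 = 1; delta = 1 - mean(other R^2) in (0, 1]
        assert 0 < res.delta[0] <= 1.0

    def test_intersection_mask(self, rng):
        tables = make_tables(rng, S=3, P=6, effect=0.8)
        raw = fisher_average_map(tables, n_perm=80, seed=3)
        res = participant_specific_delta(tables, n_perm=80, seed=3, raw_map=raw)
        assert res.intersection is not None
        assert not (res.intersection & ~res.sig).any()
        assert not (res.intersection & ~raw.sig).any()
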