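"""AUROC, DeLong, repeated-split classification, comparators and LOOCV NRMSE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bfsig.classify import (RepeatedSplitClassifier, auroc,
                            build_comparator_features, delong_ci, delong_test,
                            loocv_nrmse, nrmse, repeated_split_evaluate)
from bfsig.io import ExpressionMatrix


def brute_force_auroc(scores, labels):
    scores = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([.9, .8, .4, .3], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert auroc([.9, .35, .4, .3], [1, 1, 0, 0]) == 0.75

    def test_single_tie_gives_half(self):
        assert auroc([.5, .5], [1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([1, 2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 50)
        y = np.zeros(n, int)
        y[: rng.integers(1, n)] = 1
        rng.shuffle(y)
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        assert auroc(scores, y) == pytest.approx(brute_force_auroc(scores, y),
                                                 abs=1e-12)


def stratified_bootstrap_p(sa, sb, y, n_draws=100_000, seed=0):
    """Two-sided bootstrap p for the AUROC difference (paired, stratified)."""
    rng = np.random.default_rng(seed)
    sa, sb, y = np.asarray(sa, float), np.asarray(sb, float), np.asarray(y, int)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    ip = pos[rng.integers(0, len(pos), size=(n_draws, len(pos)))]
    iq = neg[rng.integers(0, len(neg), size=(n_draws, len(neg)))]

    def aucs(s):
        p = s[ip][:, :, None]
        q = s[iq][:, None, :]
        return ((p > q) + 0.5 * (p == q)).mean(axis=(1, 2))

    diff = aucs(sa) - aucs(sb)
    lo = (diff <= 0).mean()
    hi = (diff >= 0).mean()
    return min(1.0, 2 * min(lo, hi))


class TestDelong:
    def test_identical_models_p_one(self):
        y = [1, 1, 0, 0, 1, 0]
        s = [.9, .7, .6, .2, .8, .4]
        a, b, z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0 and a == b

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        y = np.array([1] * 6 + [0] * 6)
        sa = rng.normal(y, 1.0)
        sb = rng.normal(y * 0.3, 1.0)
        a1, b1, z1, p1 = delong_test(sa, sb, y)
        a2, b2, z2, p2 = delong_test(sb, sa, y)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_p_close_to_bootstrap_oracle(self):
        # fixed small instance, n=8 (4 pos / 4 neg)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        sa = np.array([0.92, 0.81, 0.58, 0.46, 0.52, 0.38, 0.27, 0.15])
        sb = np.array([0.65, 0.42, 0.71, 0.33, 0.60, 0.51, 0.44, 0.30])
        *_, p = delong_test(sa, sb, y)
        p_boot = stratified_bootstrap_p(sa, sb, y, seed=0)
        assert p == pytest.approx(p_boot, abs=0.02)

    def test_single_model_variance_close_to_hanley_mcneil(self):
        rng = np.random.default_rng(7)
        y = np.array([1] * 30 + [0] * 30)
        s = rng.normal(1.2 * y, 1.0)
        theta, var, ci = delong_ci(s, y)
        q1 = theta / (2 - theta)
        q2 = 2 * theta**2 / (1 + theta)
        n1 = n0 = 30
        hm = (theta * (1 - theta) + (n1 - 1) * (q1 - theta**2)
              + (n0 - 1) * (q2 - theta**2)) / (n1 * n0)
        assert var == pytest.approx(hm, rel=0.25)
        assert ci[0] < theta < ci[1]


class TestRepeatedSplit:
    def test_separable_features_pool_to_perfect_auroc(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(5, .3, size=(20, 2)),
                       rng.normal(0, .3, size=(20, 2))])
        y = np.array([1] * 20 + [0] * 20)
        ev = repeated_split_evaluate(X, y, seed=1)
        assert ev.pooled_auroc == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        aucs = []
        for seed in range(10):
            X = rng.normal(size=(60, 3))
            y = np.array([1] * 30 + [0] * 30)
            rng.shuffle(y)
            aucs.append(repeated_split_evaluate(X, y, seed=seed).pooled_auroc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        y = np.array([1] * 20 + [0] * 20)
        e1 = repeated_split_evaluate(X, y, seed=9)
        e2 = repeated_split_evaluate(X, y, seed=9)
        assert e1.pooled_auroc == e2.pooled_auroc
        pd.testing.assert_series_equal(e1.sample_probability, e2.sample_probability)
        assert all(np.array_equal(a[1], b[1]) for a, b in zip(e1.splits, e2.splits))

    def test_probability_averaging_uses_test_appearances_only(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = np.array([1] * 15 + [0] * 15)
        ev = repeated_split_evaluate(X, y, seed=4)
        counts = np.zeros(30)
        acc = np.zeros(30)
        for (train, test), probs in zip(
                ev.splits, np.split(ev.pooled_scores,
                                    np.cumsum([len(t) for _, t in ev.splits])[:-1])):
            counts[test] += 1
            acc[test] += probs
        expected = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
        np.testing.assert_allclose(ev.sample_probability.to_numpy(), expected,
                                   equal_nan=True)

    def test_coefficient_sign_recovery(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 3))
            beta = np.array([1.5, 0.0, -1.5])
            p = 1 / (1 + np.exp(-(X @ beta)))
            y = (rng.uniform(size=300) < p).astype(int)
            clf = RepeatedSplitClassifier(random_state=seed).fit(X, y)
            coefs = np.mean(clf.evaluation_.coefficients, axis=0)
            hits += (coefs[0] > 0) and (coefs[2] < 0)
        assert hits >= 9


class TestComparators:
    @pytest.fixture
    def expr(self, rng):
        genes = ["BCL2", "MCL1", "BCL2A1", "BCL2L1", "BCL2L2", "AAA", "BBB"]
        return ExpressionMatrix(rng.uniform(1, 5, size=(7, 8)), genes,
                                [f"S{j}" for j in range(8)])

    def test_anchor_modes(self, expr):
        f3 = build_comparator_features(expr, mode="anchors3")
        assert list(f3.columns) == ["BCL2", "MCL1", "BCL2A1"]
        f5 = build_comparator_features(expr, mode="anchors5")
        assert f5.shape == (8, 5)

    def test_topn_deg_ranks_by_mean_difference(self, rng):
        vals = np.ones((3, 6))
        vals[1, :3] += 2.0   # gene B: strong difference
        vals[2, :3] += 0.5   # gene C: weak difference
        em = ExpressionMatrix(vals, ["A", "B", "C"], [f"S{j}" for j in range(6)])
        y = [1, 1, 1, 0, 0, 0]
        top = build_comparator_features(em, y, mode="topN_deg", n_top=2)
        assert list(top.columns) == ["B", "C"]  # zero-difference A never first

    def test_topn_exceeding_gene_count_warns(self, expr):
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        with pytest.warns(UserWarning, match="exceeds"):
            out = build_comparator_features(expr, y, mode="topN_deg", n_top=99)
        assert out.shape[1] == expr.n_genes

    def test_missing_anchor_raises(self, rng):
        em = ExpressionMatrix(rng.uniform(1, 2, (2, 3)), ["BCL2", "MCL1"],
                              ["a", "b", "c"])
        with pytest.raises(KeyError, match="BCL2A1"):
            build_comparator_features(em, mode="anchors3")


class TestLoocvNrmse:
    def test_exact_linear_response(self, rng):
        X = rng.normal(size=(12, 2))
        y = X @ np.array([2.0, -1.0]) + 3.0
        assert loocv_nrmse(X, y).nrmse < 1e-8

    def test_fixture_value(self):
        # RMSE((1,1,1),(0,1,2)) = sqrt(2/3), range 2 -> 0.408
        assert nrmse([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]) == pytest.approx(
            0.408, abs=5e-4)

    def test_noise_features_bounded_by_intercept_only(self, rng):
        y = rng.normal(size=30)
        X = rng.normal(size=(30, 2))
        got = loocv_nrmse(X, y).nrmse
        # intercept-only LOOCV: predict mean of the other n-1 points
        n = len(y)
        preds = (y.sum() - y) / (n - 1)
        base = np.sqrt(np.mean((preds - y) ** 2)) / np.ptp(y)
        assert got >= base * 0.95

    def test_zero_range_rejected(self, rng):
        with pytest.raises(ValueError, match="range"):
            loocv_nrmse(rng.normal(size=(10, 1)), np.full(10, 3.0))
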