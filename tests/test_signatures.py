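"""Connectivity/consensus, rank rule, extraction, labeling and concordance."""

import numpy as np
import pandas as pd
import pytest

from bfsig.io import ExpressionMatrix
from bfsig.signatures import (RankSelectionReport, SignatureSet,
                              _cophenetic_of_consensus, connectivity_matrix,
                              consensus_and_cophenetic, extract_signatures,
                              label_signatures, select_rank,
                              signature_concordance)
from bfsig.simulate import simulate_bfsig_dataset


class TestConnectivity:
    def test_argmax_grouping(self):
        H = np.array([[.9, .8, .1], [.1, .2, .9]])
        expect = [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        np.testing.assert_array_equal(connectivity_matrix(H), expect)

    def test_single_dominant_factor_all_ones(self):
        H = np.array([[.9, .8, .7], [.1, .2, .3]])
        assert (connectivity_matrix(H) == 1).all()

    def test_tie_goes_to_lowest_index(self):
        H = np.array([[.5, .9], [.5, .1]])
        C = connectivity_matrix(H)
        assert C[0, 1] == 1  # tied sample joins factor 0 like sample 2

    def test_all_zero_sample_rejected(self):
        H = np.array([[1.0, 0.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="all-zero"):
            connectivity_matrix(H)


class TestConsensusCophenetic:
    def test_block_diagonal_consensus_scores_one(self):
        C = np.kron(np.eye(3), np.ones((4, 4)))
        assert _cophenetic_of_consensus(C) == 1.0

    def test_duplicate_seeds_give_binary_consensus(self):
        expr, *_ = simulate_bfsig_dataset(n_samples=30, n_signal=6, n_noise=0,
                                          seed=0)
        cons, _ = consensus_and_cophenetic(expr, 2, n_runs=2, seed=5,
                                           max_iter=300)
        # two runs only: entries are multiples of 1/2
        assert set(np.round(np.unique(cons * 2)).astype(int)) <= {0, 1, 2}
        assert np.allclose(cons, cons.T) and np.allclose(np.diag(cons), 1)
        assert cons.min() >= 0 and cons.max() <= 1

    def test_true_rank_more_stable_than_overfit_rank(self):
        hits = 0
        for seed in range(3):
            expr, pool, truth = simulate_bfsig_dataset(
                n_samples=80, n_signal=12, n_noise=0, seed=seed)
            _, c3 = consensus_and_cophenetic(expr, 3, n_runs=8, seed=seed,
                                             max_iter=500, tol=1e-5)
            _, c5 = consensus_and_cophenetic(expr, 5, n_runs=8, seed=seed,
                                             max_iter=500, tol=1e-5)
            hits += c3 > c5
        assert hits >= 2


class TestSelectRank:
    def test_first_fall_rule_on_fixed_profile(self, monkeypatch):
        coph = {2: 0.99, 3: 0.99, 4: 0.80, 5: 0.78}

        def fake(A, k, **kw):
            return np.eye(3), coph[k]

        monkeypatch.setattr("bfsig.signatures.consensus_and_cophenetic", fake)
        rep = select_rank(np.ones((4, 3)), range(2, 6), drop_tol=0.05)
        assert rep.chosen_rank == 3

    def test_no_fall_defaults_to_max_with_warning(self, monkeypatch):
        monkeypatch.setattr("bfsig.signatures.consensus_and_cophenetic",
                            lambda A, k, **kw: (np.eye(3), 0.99))
        with pytest.warns(UserWarning, match="never fell"):
            rep = select_rank(np.ones((4, 3)), range(2, 5), drop_tol=0.02)
        assert rep.chosen_rank == 4

    def test_single_rank_rejected(self):
        with pytest.raises(ValueError):
            select_rank(np.ones((4, 3)), [3])


class TestExtractAndLabel:
    def test_weights_sum_to_one_and_reconstruction_preserved(self):
        expr, *_ = simulate_bfsig_dataset(n_samples=40, n_signal=8, n_noise=0,
                                          seed=1)
        sigs = extract_signatures(expr, 3, restarts=2, seed=1, max_iter=500)
        np.testing.assert_allclose(sigs.W_norm.to_numpy().sum(axis=0), 1.0,
                                   atol=1e-9)

    def test_label_by_anchor_dominance(self):
        W = pd.DataFrame(
            [[0.9, 0.05, 0.05],   # BCL2 concentrates in sig 1
             [0.05, 0.9, 0.05],   # MCL1 in sig 2
             [0.05, 0.05, 0.9],   # BFL1 (BCL2A1) in sig 3
             [1/3, 1/3, 1/3]],
            index=["BCL2", "MCL1", "BCL2A1", "OTHER"],
            columns=["sig_1", "sig_2", "sig_3"])
        W = W / W.sum(axis=0)
        H = pd.DataFrame(np.ones((3, 4)), index=W.columns)
        sigs = SignatureSet(W, H, list(W.columns), 3)
        out = label_signatures(sigs, anchors=("BCL2", "MCL1", "BCL2A1"),
                               composite_ratio=0.99)
        assert out.labels == ["BCL2", "MCL1", "BFL1"]

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        W = np.abs(rng.normal(size=(6, 3))) + 0.01
        W[:3] = np.eye(3) * 5 + 0.01
        W = W / W.sum(axis=0)
        idx = ["BCL2", "MCL1", "BCL2A1", "X1", "X2", "X3"]
        perm = [2, 0, 1]
        s1 = SignatureSet(pd.DataFrame(W, index=idx, columns=["sig_1", "sig_2", "sig_3"]),
                          pd.DataFrame(np.ones((3, 2)), index=["sig_1", "sig_2", "sig_3"]),
                          ["sig_1", "sig_2", "sig_3"], 3)
        Wp = W[:, perm] / W[:, perm].sum(axis=0)
        s2 = SignatureSet(pd.DataFrame(Wp, index=idx, columns=["sig_1", "sig_2", "sig_3"]),
                          pd.DataFrame(np.ones((3, 2)), index=["sig_1", "sig_2", "sig_3"]),
                          ["sig_1", "sig_2", "sig_3"], 3)
        l1 = label_signatures(s1, anchors=("BCL2", "MCL1", "BCL2A1"))
        l2 = label_signatures(s2, anchors=("BCL2", "MCL1", "BCL2A1"))
        m1 = {lab: tuple(np.round(l1.W_norm[lab], 6)) for lab in l1.labels}
        m2 = {lab: tuple(np.round(l2.W_norm[lab], 6)) for lab in l2.labels}
        assert m1 == m2

    def test_no_anchors_falls_back_to_generic(self):
        W = pd.DataFrame(np.full((4, 2), 0.25), index=list("wxyz"),
                         columns=["sig_1", "sig_2"])
        H = pd.DataFrame(np.ones((2, 3)), index=W.columns)
        sigs = SignatureSet(W, H, list(W.columns), 2)
        with pytest.warns(UserWarning, match="no anchors"):
            out = label_signatures(sigs, anchors=("BCL2",))
        assert out.labels == ["sig_1", "sig_2"]

    def test_recovers_generator_loadings_up_to_permutation(self):
        from scipy.optimize import linear_sum_assignment

        expr, pool, truth = simulate_bfsig_dataset(n_samples=80, n_signal=12,
                                                   n_noise=0, seed=3)
        sigs = extract_signatures(expr, 3, restarts=3, seed=3, max_iter=1000)
        West = sigs.W_norm.to_numpy()
        Wtrue = truth.W_true / truth.W_true.sum(axis=0)
        corr = np.corrcoef(West.T, Wtrue.T)[:3, 3:]
        rows, cols = linear_sum_assignment(-corr)
        assert (corr[rows, cols] > 0.9).all()


class TestConcordance:
    def test_identical_weights_give_unit_diagonal(self, rng):
        W = pd.DataFrame(rng.uniform(size=(8, 2)), columns=["a", "b"],
                         index=[f"g{i}" for i in range(8)])
        rho = signature_concordance(W, W)
        np.testing.assert_allclose(np.diag(rho.to_numpy(dtype=float)), 1.0)

    def test_reversed_ranking_gives_minus_one(self, rng):
        w = rng.uniform(size=8)
        W1 = pd.DataFrame({"s": w}, index=[f"g{i}" for i in range(8)])
        W2 = pd.DataFrame({"s": w.max() - w}, index=W1.index)
        assert signature_concordance(W1, W2).iloc[0, 0] == pytest.approx(-1.0)

    def test_small_intersection_rejected(self):
        W1 = pd.DataFrame({"s": [1, 2, 3]}, index=list("abc"))
        with pytest.raises(ValueError, match="shared genes"):
            signature_concordance(W1, W1)
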