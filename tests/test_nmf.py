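"""Masked KL-NMF: loss, fitting, completion, projection and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bfsig.nmf import (MaskedNMF, fit_masked_nmf, impute_missing_entries,
                       mean_kl_divergence, project_onto_fixed_basis)


def rank_k_product(rng, g, n, k, scale=1.0):
    W = rng.gamma(2.0, scale, size=(g, k))
    H = rng.gamma(2.0, scale, size=(k, n))
    return W, H, W @ H


class TestMeanKL:
    def test_zero_iff_equal(self, rng):
        A = rng.uniform(0.1, 3, size=(4, 5))
        assert mean_kl_divergence(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_pointwise_formula(self):
        # d(2, 1) = 2 ln 2 - 2 + 1
        assert mean_kl_divergence([[2.0]], [[1.0]]) == pytest.approx(
            2 * np.log(2) - 1, abs=1e-12)
        # 0 * ln 0 convention: d(0, 1) = 1
        assert mean_kl_divergence([[0.0]], [[1.0]]) == pytest.approx(1.0)

    def test_mask_restricts_the_mean(self):
        A = np.array([[2.0, 7.0]])
        Ahat = np.array([[1.0, 1.0]])
        mask = np.array([[True, False]])
        assert mean_kl_divergence(A, Ahat, mask) == pytest.approx(2 * np.log(2) - 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            mean_kl_divergence(np.ones((2, 2)), np.ones((2, 2)),
                               np.zeros((2, 2), bool))


class TestFit:
    def test_constant_matrix_rank_one(self):
        A = np.full((6, 5), 2.5)
        m = fit_masked_nmf(A, 1, seed=0)
        np.testing.assert_allclose(m.reconstruction(), A, atol=1e-6)

    @pytest.mark.parametrize("g,n,k", [(20, 15, 2), (30, 20, 3)])
    def test_exact_recovery_of_generating_product(self, rng, g, n, k):
        _, _, A = rank_k_product(rng, g, n, k)
        m = fit_masked_nmf(A, k, seed=1, n_restarts=3)
        assert m.reconstruction_err_ < 1e-6

    def test_masked_fit_recovers_heldout_entries(self, rng):
        _, _, A = rank_k_product(rng, 20, 15, 2)
        mask = rng.uniform(size=A.shape) > 0.2
        m = fit_masked_nmf(A, 2, mask=mask, seed=2, n_restarts=3)
        assert mean_kl_divergence(A, m.reconstruction(), mask) < 1e-6
        held = ~mask
        rel = np.abs(m.reconstruction()[held] - A[held]) / A[held]
        assert np.median(rel) < 1e-3

    def test_loss_trace_monotone(self, rng):
        _, _, A = rank_k_product(rng, 15, 12, 2)
        m = fit_masked_nmf(A, 2, seed=3, n_restarts=1)
        trace = np.array(m.loss_trace_)
        # relative slack plus an absolute floor for the machine-zero regime
        assert np.all(np.diff(trace) <= 1e-10 * trace[:-1] + 1e-12)

    def test_nonnegativity(self, rng):
        _, _, A = rank_k_product(rng, 10, 8, 2)
        m = fit_masked_nmf(A, 2, seed=4)
        assert (m.W_ >= 0).all() and (m.H_ >= 0).all()

    def test_masked_entries_have_zero_influence(self, rng):
        _, _, A = rank_k_product(rng, 10, 8, 2)
        mask = np.ones_like(A, bool)
        mask[3, 4] = False
        m1 = fit_masked_nmf(A, 2, mask=mask, seed=5)
        A2 = A.copy()
        A2[3, 4] = 999.0
        m2 = fit_masked_nmf(A2, 2, mask=mask, seed=5)
        np.testing.assert_array_equal(m1.W_, m2.W_)
        np.testing.assert_array_equal(m1.H_, m2.H_)

    def test_scale_indeterminacy_of_reconstruction(self, rng):
        m = fit_masked_nmf(rank_k_product(rng, 10, 8, 2)[2], 2, seed=6)
        d = np.array([2.0, 0.5])
        np.testing.assert_allclose((m.W_ * d) @ (m.H_ / d[:, None]),
                                   m.reconstruction(), rtol=1e-12)

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError, match="rank"):
            MaskedNMF(rank=9).fit(np.ones((3, 3)))

    def test_same_seed_reproducible(self, rng):
        A = rank_k_product(rng, 12, 9, 2)[2]
        m1 = fit_masked_nmf(A, 2, seed=11)
        m2 = fit_masked_nmf(A, 2, seed=11)
        np.testing.assert_array_equal(m1.W_, m2.W_)


class TestImpute:
    def test_rank1_completion_forced_by_proportionality(self):
        A = np.array([[1.0, 2.0], [2.0, np.nan]])
        out = impute_missing_entries(A, 1, seed=0)
        assert out[1, 1] == pytest.approx(4.0, abs=1e-3)
        assert out[0, 0] == 1.0 and out[1, 0] == 2.0  # observed untouched

    def test_no_missing_is_identity(self, rng):
        A = rank_k_product(rng, 6, 5, 2)[2]
        np.testing.assert_array_equal(impute_missing_entries(A, 2, seed=0), A)

    def test_fully_missing_row_rejected(self):
        A = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="fully missing"):
            impute_missing_entries(A, 1)

    def test_recovery_on_low_rank_row(self, rng):
        W, H, A = rank_k_product(rng, 50, 30, 3)
        Am = A.copy()
        miss = rng.choice(30, size=3, replace=False)
        Am[0, miss] = np.nan
        out = impute_missing_entries(Am, 3, seed=1, n_restarts=3)
        r = np.corrcoef(out[0, miss], A[0, miss])[0, 1]
        assert r > 0.95


class TestProjection:
    def test_recovers_generating_activities(self, rng):
        W = rng.gamma(2.0, 1.0, size=(20, 2))
        H0 = rng.gamma(2.0, 1.0, size=(2, 7))
        H = project_onto_fixed_basis(W @ H0, W, max_iter=5000, tol=1e-12)
        np.testing.assert_allclose(H, H0, atol=1e-3)

    def test_all_zero_input_gives_zero_activities(self):
        H = project_onto_fixed_basis(np.zeros((4, 3)), np.ones((4, 2)))
        assert (H == 0).all()

    def test_unit_basis_gives_column_means(self, rng):
        A = rng.uniform(1, 4, size=(6, 5))
        H = project_onto_fixed_basis(A, np.ones((6, 1)), max_iter=5000, tol=1e-12)
        np.testing.assert_allclose(H.ravel(), A.mean(axis=0), rtol=1e-6)

    def test_gene_mismatch_raises(self):
        with pytest.raises(ValueError, match="gene mismatch"):
            project_onto_fixed_basis(np.ones((4, 2)), np.ones((5, 2)))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_loss_trace_monotone_property(seed):
    """Multiplicative KL updates never increase the observed-entry loss."""
    rng = np.random.default_rng(seed)
    A = rng.gamma(2.0, 1.0, size=(8, 6))
    mask = rng.uniform(size=A.shape) > 0.15
    mask[0, :3] = True  # keep mask non-degenerate
    m = fit_masked_nmf(A, 2, mask=mask, seed=seed, n_restarts=1, max_iter=300)
    trace = np.array(m.loss_trace_)
    assert np.all(np.diff(trace) <= 1e-10 * trace[:-1] + 1e-12)
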