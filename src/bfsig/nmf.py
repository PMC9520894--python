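"""Non-negative matrix factorization with mean Kullback-Leibler loss and
support for missing entries.

The factorization A ~= W @ H (A genes x samples, W genes x k, H k x samples)
is fit by multiplicative updates that minimize the mean generalized KL
divergence over *observed* entries only:

    d(a, ahat) = a * ln(a / ahat) - a + ahat        (0 * ln 0 := 0)

Masked entries contribute neither to the loss nor to the updates, which is
what makes the factorization usable for matrix completion: missing values are
filled in from the low-rank reconstruction W @ H fitted on the observed part.

The estimator follows scikit-learn conventions (``get_params``/``set_params``,
trailing-underscore fitted attributes) but keeps the field's genes x samples
orientation, so ``fit`` consumes a gene x sample array and ``transform``
returns per-sample activities H (k x n) for a frozen gene-weight basis W.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "mean_kl_divergence",
    "MaskedNMF",
    "fit_masked_nmf",
    "impute_missing_entries",
    "project_onto_fixed_basis",
]

EPS = 1e-12


def mean_kl_divergence(A, Ahat, mask=None) -> float:
    """Mean generalized KL divergence between A and Ahat over observed entries.

    Parameters
    ----------
    A, Ahat : arrays of identical shape, non-negative
    mask : boolean array, True = observed; None means fully observed.

    Returns
    -------
    float >= 0, zero iff A == Ahat on the observed entries.
    """
    A = np.asarray(A, dtype=float)
    Ahat = np.asarray(Ahat, dtype=float)
    if A.shape != Ahat.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {Ahat.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask: no observed entries")
        a = A[mask]
        ahat = Ahat[mask]
    else:
        a = A.ravel()
        ahat = Ahat.ravel()
    ahat = np.maximum(ahat, EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(a > 0, a * np.log(np.maximum(a, EPS) / ahat), 0.0)
    # each pointwise term is >= 0; summation round-off can dip below zero
    return max(float(np.mean(term - a + ahat)), 0.0)


def _init_factors(rng, g, n, k, scale):
    W = rng.uniform(0.0, 1.0, size=(g, k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, n)) * scale
    return np.maximum(W, EPS), np.maximum(H, EPS)


def _mu_kl(A, W, H, mask, max_iter, tol, update_w=True, check_every=10):
    """Multiplicative KL updates restricted to observed entries.

    Returns (W, H, loss_trace, n_iter). Loss is recorded every
    ``check_every`` iterations; convergence is declared when the relative
    loss change over one window falls below ``tol``.
    """
    full = mask is None
    if not full:
        Mf = mask.astype(float)
    ones_g = np.ones((A.shape[0], 1))
    ones_n = np.ones((1, A.shape[1]))
    if full:
        A_obs = A
    else:
        A_obs = np.where(mask, A, 0.0)

    loss_trace = []
    prev = None
    it = 0
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, EPS)
        if full:
            R = A_obs / WH
            if update_w:
                W *= (R @ H.T) / np.maximum(ones_g @ (H.sum(axis=1, keepdims=True)).T, EPS)
            WH = np.maximum(W @ H, EPS)
            R = A_obs / WH
            H *= (W.T @ R) / np.maximum((W.sum(axis=0, keepdims=True)).T @ ones_n, EPS)
        else:
            R = np.where(mask, A_obs / WH, 0.0)
            if update_w:
                W *= (R @ H.T) / np.maximum(Mf @ H.T, EPS)
            WH = np.maximum(W @ H, EPS)
            R = np.where(mask, A_obs / WH, 0.0)
            H *= (W.T @ R) / np.maximum(W.T @ Mf, EPS)
        if it % check_every == 0 or it == max_iter:
            loss = mean_kl_divergence(A, W @ H, mask)
            loss_trace.append(loss)
            if prev is not None and abs(prev - loss) <= tol * max(prev, EPS):
                break
            prev = loss
    if not loss_trace:
        loss_trace.append(mean_kl_divergence(A, W @ H, mask))
    return W, H, loss_trace, it


class MaskedNMF(BaseEstimator):
    """KL-loss NMF with an observation mask and best-of-restarts fitting.

    Parameters
    ----------
    rank : int
        Number of factors k.
    n_restarts : int, default 5
        Seeded random restarts; the fit with the lowest final observed-entry
        loss is kept.
    max_iter : int, default 2000
        Maximum multiplicative-update iterations per restart.
    tol : float, default 1e-6
        Relative mean-KL change over a 10-iteration window below which a
        restart is declared converged.
    random_state : int or None
        Seed for the factor initialization.

    Attributes
    ----------
    W_ : ndarray (g, rank)           gene weights
    H_ : ndarray (rank, n)           per-sample activities
    mask_ : ndarray (g, n) or None   observation mask used during fitting
    loss_trace_ : list of float      mean-KL trace of the winning restart
    n_iter_ : int
    reconstruction_err_ : float      final mean KL on observed entries
    """

    def __init__(self, rank=3, n_restarts=5, max_iter=2000, tol=1e-6, random_state=None):
        self.rank = rank
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, A, mask=None):
        A = np.asarray(A, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be a 2-D gene x sample array")
        g, n = A.shape
        if not (1 <= self.rank <= min(g, n)):
            raise ValueError(f"rank {self.rank} out of range [1, {min(g, n)}]")
        if np.any(A < 0):
            raise ValueError("A must be non-negative")
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != A.shape:
                raise ValueError("mask shape must match A")
            if not mask.any():
                raise ValueError("empty mask: no observed entries")
            row_obs = mask.sum(axis=1)
            col_obs = mask.sum(axis=0)
            if (row_obs < self.rank).any() or (col_obs < self.rank).any():
                warnings.warn(
                    "some rows/columns have fewer observed entries than the rank; "
                    "their factors are weakly determined"
                )
        obs = mask if mask is not None else np.ones_like(A, dtype=bool)
        zero_rows = ~np.any(np.where(obs, A, 0.0) > 0, axis=1)
        if zero_rows.any():
            warnings.warn(f"{int(zero_rows.sum())} all-zero observed rows; their W rows are zero")

        rng = np.random.default_rng(self.random_state)
        scale = np.sqrt(max(np.where(obs, A, 0.0).sum() / max(obs.sum(), 1), EPS) / self.rank)
        best = None
        for _ in range(max(1, self.n_restarts)):
            W0, H0 = _init_factors(rng, g, n, self.rank, scale)
            W, H, trace, n_iter = _mu_kl(A, W0, H0, mask, self.max_iter, self.tol)
            if best is None or trace[-1] < best[2][-1]:
                best = (W, H, trace, n_iter)
        W, H, trace, n_iter = best
        if zero_rows.any():
            W[zero_rows] = 0.0
        self.W_, self.H_ = W, H
        self.mask_ = mask
        self.loss_trace_ = trace
        self.n_iter_ = n_iter
        self.reconstruction_err_ = trace[-1]
        return self

    def fit_transform(self, A, mask=None):
        return self.fit(A, mask=mask).H_

    def transform(self, A_new, max_iter=None, tol=None):
        """Project new samples onto the fitted basis (H-only updates, W frozen)."""
        return project_onto_fixed_basis(
            A_new, self.W_,
            max_iter=max_iter or self.max_iter,
            tol=tol or self.tol,
        )

    def inverse_transform(self, H):
        return self.W_ @ np.asarray(H, dtype=float)

    def reconstruction(self):
        return self.W_ @ self.H_

    def save(self, w_path, h_path, meta_path=None, gene_ids=None, sample_ids=None):
        """Serialize W/H as TSV plus a JSON sidecar of fit metadata."""
        import pandas as pd

        k = self.W_.shape[1]
        sig = [f"sig_{i + 1}" for i in range(k)]
        pd.DataFrame(self.W_, index=gene_ids, columns=sig).to_csv(w_path, sep="\t")
        pd.DataFrame(self.H_, index=sig, columns=sample_ids).to_csv(h_path, sep="\t")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(
                    {
                        "rank": k,
                        "seed": self.random_state,
                        "n_iter": self.n_iter_,
                        "final_loss": self.reconstruction_err_,
                    },
                    fh,
                    indent=2,
                )


def fit_masked_nmf(A, k, mask=None, seed=None, max_iter=2000, tol=1e-6, n_restarts=5) -> MaskedNMF:
    """Fit KL-NMF of rank `k` on `A`, ignoring entries where `mask` is False."""
    return MaskedNMF(rank=k, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
                     random_state=seed).fit(A, mask=mask)


def impute_missing_entries(A_with_missing, k, n_restarts=5, seed=None,
                           max_iter=2000, tol=1e-6) -> np.ndarray:
    """Complete a matrix with NaN-marked missing entries by masked KL-NMF.

    Missing entries are replaced by the reconstruction W @ H at those
    positions, taking the restart with the lowest final observed-entry loss.
    """
    A = np.asarray(A_with_missing, dtype=float)
    missing = np.isnan(A)
    if not missing.any():
        return A.copy()
    fully_missing = missing.all(axis=1)
    if fully_missing.any():
        raise ValueError(
            f"rows fully missing, imputation undefined: {np.flatnonzero(fully_missing).tolist()}"
        )
    mask = ~missing
    A_filled = np.where(missing, 0.0, A)
    model = fit_masked_nmf(A_filled, k, mask=mask, seed=seed, max_iter=max_iter,
                           tol=tol, n_restarts=n_restarts)
    out = A.copy()
    out[missing] = model.reconstruction()[missing]
    return out


def project_onto_fixed_basis(A_new, W_fixed, max_iter=2000, tol=1e-6) -> np.ndarray:
    """Estimate activities H for new samples under a frozen gene basis W.

    H-only multiplicative KL updates from a deterministic flat
    initialization, so the projection is reproducible without a seed.
    """
    A = np.asarray(A_new, dtype=float)
    W = np.asarray(W_fixed, dtype=float)
    if A.shape[0] != W.shape[0]:
        raise ValueError(
            f"gene mismatch: A has {A.shape[0]} rows but W_fixed has {W.shape[0]}"
        )
    if not A.any():
        return np.zeros((W.shape[1], A.shape[1]))
    k = W.shape[1]
    H = np.full((k, A.shape[1]), A.mean() / max(W.mean() * k, EPS))
    _, H, _, _ = _mu_kl(A, W.copy(), H, None, max_iter, tol, update_w=False)
    return H
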