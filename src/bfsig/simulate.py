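"""Synthetic expression data with the latent structure the signature
analysis assumes, plus ground truth for every stage.

The generator draws k latent factor activities per sample from a mixture of
Dirichlet components (each component dominated by one factor, so samples
fall into k groups), builds gene loadings by role --

* anchor genes: one-hot-dominant rows, each tied to a single factor, named
  after the anti-apoptotic BCL2-family members;
* signal genes: rows concentrated on one factor with random cross-loadings,
  i.e. co-regulated with the anchors;
* noise genes: flat rows, so after the (near-constant) per-sample total
  activity their systematic variation is nil; they are "high-noise" genes
  whose observed variation comes from the measurement noise model plus
  shared confounder variation that is independent of the latent factors --

and emits expression = (W_true @ H_true) perturbed by multiplicative
lognormal noise (default) or a gamma-Poisson count model.  Optional batch
shifts are applied last.  Drug response is simulated from the true factor
activities: a logistic model for binary sensitive/resistant calls mapped to
IC50 values on either side of the 1/10 uM thresholds, or a linear model for
continuous AUC.

Everything random flows from a single seed; the same seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEFAULT_ANCHORS, ExpressionMatrix, GeneSet, ResponseTable

__all__ = ["SyntheticTruth", "simulate_bfsig_dataset", "simulate_drug_response", "bayes_auroc"]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    W_true: np.ndarray            # genes x k loadings
    H_true: np.ndarray            # k x n activities
    gene_roles: dict              # gene_id -> {"anchor", "signal", "noise"}
    anchor_factor: dict           # anchor gene_id -> factor index
    signal_factor: dict           # signal gene_id -> factor index
    sample_group: np.ndarray      # n, dominant mixture component per sample
    batch_of: dict | None         # sample_id -> batch label (None if no batches)
    batch_params: dict | None     # batch label -> (shift, scale)
    response_beta: np.ndarray | None = None
    response_noise: float | None = None
    seed: int | None = None
    config: dict = field(default_factory=dict)


def _dirichlet_like(rng, k, group, separation, n):
    """Mixture activities: each sample's component puts mass `separation` on
    its group factor. Columns sum to 1 before scaling by total activity."""
    alpha = np.full((n, k), 1.0)
    alpha[np.arange(n), group] += separation
    raw = rng.gamma(shape=alpha, scale=1.0)
    return (raw / raw.sum(axis=1, keepdims=True)).T


def simulate_bfsig_dataset(
    n_samples: int = 200,
    n_signal: int = 30,
    n_noise: int = 30,
    k: int = 3,
    anchors=DEFAULT_ANCHORS,
    separation: float = 8.0,
    anchor_dominance: float = 1.0,
    anchor_background: float = 0.03,
    signal_dominance: float = 0.8,
    total_activity: float = 10.0,
    noise_model: str = "lognormal",
    noise_scale: float = 0.2,
    confounder_strength: float = 0.8,
    n_confounders: int = 3,
    batches: dict | None = None,
    seed: int | None = None,
):
    """Simulate one (ExpressionMatrix, GeneSet, SyntheticTruth) triple.

    Parameters
    ----------
    n_samples, n_signal, n_noise, k : dataset dimensions; `k >= 2` and
        `n_samples >= 3 k` are required so every factor has enough samples.
    separation : Dirichlet concentration placed on each sample's own factor;
        the single "difficulty" knob — larger means better-separated groups.
    anchor_dominance, anchor_background : loading of an anchor on its mapped
        factor vs. the flat background on the others.
    signal_dominance : expected loading of a signal gene on its factor,
        drawn Gamma-distributed around this value with cross-loading noise.
    total_activity : per-sample sum of factor activities (held constant so
        flat-loaded noise genes carry no factor signal).
    noise_model : "lognormal" multiplicative noise with sigma `noise_scale`,
        or "gamma-poisson" overdispersed counts (Gamma shape
        1/noise_scale**2, then Poisson).
    confounder_strength, n_confounders : what makes noise genes "high-noise":
        their multiplicative noise carries a shared lognormal confounder
        (log-sd `confounder_strength`, `n_confounders` independent latent
        confounders assigned round-robin) that is independent of the k true
        factors but structured across samples — exactly the kind of
        variation that distorts a low-rank fit and that backward selection
        should remove.  Disabled when `noise_scale` is 0 (noiseless limit).
    batches : optional {"n_batches": int, "shift": float, "scale": float};
        samples are split evenly and non-first batches get
        `x -> x * scale_b + shift_b` perturbations.
    seed : master seed; identical seeds give bit-identical outputs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_samples < 3 * k:
        raise ValueError(f"n_samples ({n_samples}) must be >= 3*k ({3 * k})")
    anchors = tuple(anchors)
    if len(anchors) == 0:
        raise ValueError("need at least one anchor")
    rng = np.random.default_rng(seed)

    # balanced sample groups, one per latent factor
    group = np.arange(n_samples) % k
    rng.shuffle(group)
    H = _dirichlet_like(rng, k, group, separation, n_samples) * total_activity

    anchor_factor = {a: i % k for i, a in enumerate(anchors)}
    signal_ids = [f"SIG{i + 1:03d}" for i in range(n_signal)]
    noise_ids = [f"NOISE{i + 1:03d}" for i in range(n_noise)]
    signal_factor = {g: i % k for i, g in enumerate(signal_ids)}

    gene_ids = list(anchors) + signal_ids + noise_ids
    g = len(gene_ids)
    W = np.zeros((g, k))
    roles = {}
    for i, a in enumerate(anchors):
        W[i] = anchor_background
        W[i, anchor_factor[a]] = anchor_dominance
        roles[a] = "anchor"
    for j, s in enumerate(signal_ids):
        i = len(anchors) + j
        W[i] = rng.gamma(shape=1.5, scale=signal_dominance / 8.0, size=k)
        W[i, signal_factor[s]] += rng.gamma(shape=4.0, scale=signal_dominance / 4.0)
        roles[s] = "signal"
    flat = (anchor_dominance + 2 * anchor_background) / k
    for j, nz in enumerate(noise_ids):
        i = len(anchors) + n_signal + j
        W[i] = flat * rng.uniform(0.5, 1.5)  # flat across factors => no factor signal
        roles[nz] = "noise"

    signal_matrix = W @ H
    noise_rows = np.arange(len(anchors) + n_signal, g)
    if noise_scale == 0:
        A = signal_matrix.copy()
    else:
        mean = signal_matrix.copy()
        if confounder_strength > 0 and len(noise_rows) and n_confounders > 0:
            U = rng.normal(size=(n_confounders, n_samples))
            for j, i in enumerate(noise_rows):
                mean[i] = mean[i] * np.exp(confounder_strength * U[j % n_confounders])
        if noise_model == "lognormal":
            A = mean * rng.lognormal(mean=0.0, sigma=noise_scale, size=mean.shape)
        elif noise_model == "gamma-poisson":
            shape = 1.0 / max(noise_scale, 1e-6) ** 2
            lam = rng.gamma(shape=shape, scale=np.maximum(mean, 1e-9) / shape)
            A = rng.poisson(lam).astype(float)
        else:
            raise ValueError(f"unknown noise_model {noise_model!r}")

    sample_ids = [f"S{j + 1:04d}" for j in range(n_samples)]
    batch_of = batch_params = None
    if batches:
        nb = int(batches.get("n_batches", 2))
        shift = float(batches.get("shift", 2.0))
        scale = float(batches.get("scale", 1.3))
        labels = [f"batch{j % nb + 1}" for j in range(n_samples)]
        batch_of = dict(zip(sample_ids, labels))
        batch_params = {}
        for b in range(nb):
            sh, sc = (0.0, 1.0) if b == 0 else (shift * b, scale**b)
            batch_params[f"batch{b + 1}"] = (sh, sc)
            cols = [j for j in range(n_samples) if j % nb == b]
            A[:, cols] = A[:, cols] * sc + sh
    A = np.maximum(A, 0.0)

    expr = ExpressionMatrix(A, gene_ids, sample_ids)
    gene_set = GeneSet(frozenset(gene_ids), anchors)
    truth = SyntheticTruth(
        W_true=W, H_true=H, gene_roles=roles, anchor_factor=anchor_factor,
        signal_factor=signal_factor, sample_group=group,
        batch_of=batch_of, batch_params=batch_params, seed=seed,
        config={
            "n_samples": n_samples, "n_signal": n_signal, "n_noise": n_noise,
            "k": k, "separation": separation, "noise_model": noise_model,
            "noise_scale": noise_scale, "total_activity": total_activity,
            "confounder_strength": confounder_strength,
            "n_confounders": n_confounders,
        },
    )
    return expr, gene_set, truth


def simulate_drug_response(
    truth: SyntheticTruth,
    sample_ids,
    mode: str = "binary",
    beta=None,
    noise: float = 1.0,
    drug: str = "venetoclax",
    repeat_fraction: float = 0.1,
    seed: int | None = None,
) -> ResponseTable:
    """Simulate per-sample drug response from the true factor activities.

    binary mode: P(sensitive) = sigmoid(beta . (H - mean H) + eps),
    eps ~ N(0, noise); sensitive samples get IC50 drawn <= 1 uM and
    resistant ones >= 10 uM.  continuous mode: AUC = beta . H + eps.
    A `repeat_fraction` of patients contribute a second, later-time-point
    sample in the same response class so downstream de-duplication has work
    to do; all other patients have one sample at time point 1.
    """
    H = truth.H_true
    k = H.shape[0]
    if beta is None:
        beta = np.zeros(k)
        beta[0] = 0.4      # factor 1 drives sensitivity
        beta[-1] = -0.4    # last factor drives resistance
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (k,):
        raise ValueError(f"beta must have length k={k}")
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if H.shape[1] != n:
        raise ValueError("sample_ids length must match H_true columns")
    rng = np.random.default_rng(seed)

    centered = H - H.mean(axis=1, keepdims=True)
    score = beta @ centered
    rows = []
    if mode == "binary":
        p = 1.0 / (1.0 + np.exp(-(score + rng.normal(0.0, noise, size=n))))
        sensitive = rng.uniform(size=n) < p
        ic50 = np.where(sensitive,
                        10 ** rng.uniform(-2.0, 0.0, size=n),
                        10 ** rng.uniform(1.0, 2.5, size=n))
        for j, sid in enumerate(sample_ids):
            rows.append((sid, f"P{j + 1:04d}", 1, drug, ic50[j], np.nan))
        # later-time-point repeats of the same patients, same response side
        n_rep = int(round(repeat_fraction * n))
        for r, j in enumerate(rng.choice(n, size=n_rep, replace=False)):
            lo, hi = ((-2.0, 0.0) if sensitive[j] else (1.0, 2.5))
            rows.append((f"S{n + r + 1:04d}R", f"P{j + 1:04d}", 2, drug,
                         10 ** rng.uniform(lo, hi), np.nan))
    elif mode == "continuous":
        auc = score + rng.normal(0.0, noise, size=n)
        for j, sid in enumerate(sample_ids):
            rows.append((sid, f"P{j + 1:04d}", 1, drug, np.nan, auc[j]))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    df = pd.DataFrame(rows, columns=["sample_id", "patient_id", "time_point",
                                     "drug", "ic50_uM", "auc"])
    truth.response_beta = beta
    truth.response_noise = noise
    return ResponseTable(df)


def bayes_auroc(truth: SyntheticTruth, beta=None, noise: float | None = None,
                n_mc: int = 200_000, seed: int = 0) -> float:
    """AUROC of the true linear score under the generating label model.

    This is the performance ceiling for any classifier built on the factor
    activities: labels are drawn from the same logistic model that
    `simulate_drug_response` uses, on a large Monte Carlo resample of the
    fitted dataset's activity distribution, and the true score is used as
    the predictor.
    """
    from .classify import auroc

    k = truth.H_true.shape[0]
    if beta is None:
        beta = truth.response_beta
    if beta is None:
        raise ValueError("no response model recorded; pass beta")
    if noise is None:
        noise = truth.response_noise if truth.response_noise is not None else 1.0
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    cfg = truth.config
    group = rng.integers(0, k, size=n_mc)
    H = _dirichlet_like(rng, k, group, cfg.get("separation", 8.0), n_mc)
    H = H * cfg.get("total_activity", 10.0)
    score = beta @ (H - H.mean(axis=1, keepdims=True))
    p = 1.0 / (1.0 + np.exp(-(score + rng.normal(0.0, noise, size=n_mc))))
    y = (rng.uniform(size=n_mc) < p).astype(int)
    return auroc(score, y)
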