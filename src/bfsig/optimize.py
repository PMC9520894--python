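"""Imputation-guided backward selection of the signature gene set.

Starting from a pre-collected pool of BCL2-family-regulation genes, the
optimizer repeatedly asks: does the pool impute the expression profiles of
the five anchor genes well?  Anchor entries are hidden fold by fold
(v-fold partition over samples, so every anchor x sample entry is held out
exactly once), reconstructed by masked KL-NMF, and scored by per-anchor
range-normalized RMSE.  At each step the single non-anchor gene whose
removal most decreases this error is dropped; the loop stops when no
removal helps by more than `patience` or the pool reaches `min_genes`.
High-noise genes uncorrelated with the anchor factors are thereby removed,
while co-regulated signal genes survive.

All fold masks and NMF initializations are seeded, so a given
(matrix, pool, config, seed) always yields the same selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, GeneSet
from .nmf import fit_masked_nmf

__all__ = [
    "OptimizationResult",
    "fold_sample_partition",
    "build_anchor_mask_folds",
    "imputation_error",
    "optimize_gene_set",
    "GeneSetOptimizer",
]


@dataclass
class OptimizationResult:
    """Outcome of one backward-selection run."""

    selected_genes: list
    removed_genes: list              # (gene, error_after_removal) in removal order
    error_trace: list                # initial error, then error after each accepted removal
    config: dict = field(default_factory=dict)

    def to_json(self, path=None):
        payload = {
            "selected_genes": self.selected_genes,
            "removed_genes": [[g, e] for g, e in self.removed_genes],
            "error_trace": self.error_trace,
            "config": self.config,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fold_sample_partition(n_samples, v_folds=5, seed=None):
    """Seeded partition of sample indices into v folds of near-equal size."""
    if v_folds < 2:
        raise ValueError("v_folds must be >= 2")
    if v_folds > n_samples:
        raise ValueError(f"v_folds ({v_folds}) exceeds n_samples ({n_samples})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    return [np.sort(order[f::v_folds]) for f in range(v_folds)]


def build_anchor_mask_folds(n_samples, anchor_rows, n_genes, v_folds=5, seed=None):
    """Sample-wise v-fold observation masks hiding anchor-gene entries.

    Returns one boolean (n_genes x n_samples) mask per fold with True =
    observed; each fold hides the anchor rows' entries for that fold's
    samples only.  Every anchor x sample entry is hidden in exactly one
    fold, and non-anchor entries are never hidden.
    """
    anchor_rows = np.asarray(anchor_rows, dtype=int)
    masks = []
    for cols in fold_sample_partition(n_samples, v_folds, seed):
        mask = np.ones((n_genes, n_samples), dtype=bool)
        mask[np.ix_(anchor_rows, cols)] = False
        masks.append(mask)
    return masks


def imputation_error(values, anchor_rows, folds, k=3, restarts=2, seed=None,
                     max_iter=500, tol=1e-5, metric="nrmse"):
    """Anchor-profile imputation error of a candidate gene matrix.

    For each fold, the anchor entries of that fold's samples are masked and
    reconstructed by masked KL-NMF; the imputed values are pooled over folds
    and scored per anchor against the observed values.

    metric "nrmse": RMSE normalized by the anchor's observed range, averaged
    over anchors (anchors with zero range are excluded with a warning).
    metric "one_minus_pearson": 1 - Pearson r, averaged over anchors.

    `folds` is the sample partition from :func:`fold_sample_partition`
    (one array of column indices per fold); masks are built per fold for
    the candidate matrix's dimensions.
    """
    A = np.asarray(values, dtype=float)
    g, n = A.shape
    anchor_rows = np.asarray(anchor_rows, dtype=int)
    if g <= k:
        raise ValueError(f"candidate set of {g} genes not larger than rank {k}")
    imputed = np.full((len(anchor_rows), n), np.nan)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(len(folds))
    for f, cols in enumerate(folds):
        mask = np.ones((g, n), dtype=bool)
        mask[np.ix_(anchor_rows, cols)] = False
        model = fit_masked_nmf(A, k, mask=mask, seed=int(fold_seeds[f]) % (2**31),
                               max_iter=max_iter, tol=tol, n_restarts=restarts)
        rec = model.reconstruction()
        imputed[:, cols] = rec[np.ix_(anchor_rows, cols)]

    errors = []
    for i, row in enumerate(anchor_rows):
        obs = A[row]
        rng_ = obs.max() - obs.min()
        if rng_ <= 0:
            warnings.warn(f"anchor row {row} has zero range; excluded from error")
            continue
        if metric == "nrmse":
            errors.append(float(np.sqrt(np.mean((imputed[i] - obs) ** 2)) / rng_))
        elif metric == "one_minus_pearson":
            r = pearsonr(imputed[i], obs)[0]
            errors.append(float(1.0 - (0.0 if np.isnan(r) else r)))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    if not errors:
        raise ValueError("no anchor with nonzero range; imputation error undefined")
    return float(np.mean(errors))


class GeneSetOptimizer(BaseEstimator):
    """Backward gene selection minimizing anchor-imputation error.

    Parameters
    ----------
    k : int, default 3
        NMF rank used inside the imputation (the rank search's midpoint).
    v_folds : int, default 5
        Sample folds for hiding anchor entries.
    restarts : int, default 3
        NMF restarts per fold fit; fewer restarts make the error estimate
        noisy enough to stall the greedy loop early on some datasets.
    min_genes : int, default 0
        Lower bound on the surviving pool size (0 = anchors only).
    patience : float, default 0.0
        Minimal error decrease required to accept a removal.
    metric : {"nrmse", "one_minus_pearson"}
    batch_remove : bool, default False
        If True, all removals that individually improve by more than
        `patience` are applied per sweep (faster, less exact).
    random_state : int or None

    Attributes
    ----------
    result_ : OptimizationResult
    selected_genes_ : list of str
    """

    def __init__(self, k=3, v_folds=5, restarts=3, min_genes=0, patience=0.0,
                 metric="nrmse", batch_remove=False, max_iter=500, tol=1e-5,
                 random_state=None):
        self.k = k
        self.v_folds = v_folds
        self.restarts = restarts
        self.min_genes = min_genes
        self.patience = patience
        self.metric = metric
        self.batch_remove = batch_remove
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, expr: ExpressionMatrix, pool: GeneSet):
        present = [g for g in sorted(pool.members) if g in expr.gene_ids]
        dropped = sorted(pool.members - set(present))
        if dropped:
            warnings.warn(f"{len(dropped)} pool genes absent from matrix, dropped: {dropped[:5]}")
        anchors = list(pool.anchors)
        missing_anchors = [a for a in anchors if a not in expr.gene_ids]
        if missing_anchors:
            raise KeyError(f"anchor genes absent from matrix: {missing_anchors}")

        removable = sorted(set(present) - set(anchors))
        folds = fold_sample_partition(expr.n_samples, self.v_folds,
                                      seed=self.random_state)
        eval_seed = (self.random_state or 0) + 1

        def error_of(candidates):
            genes = anchors + candidates
            sub = expr.subset_genes(genes)
            return imputation_error(
                sub.values, np.arange(len(anchors)), folds, k=self.k,
                restarts=self.restarts, seed=eval_seed, max_iter=self.max_iter,
                tol=self.tol, metric=self.metric)

        config = {
            "k": self.k, "v_folds": self.v_folds, "restarts": self.restarts,
            "min_genes": self.min_genes, "patience": self.patience,
            "metric": self.metric, "seed": self.random_state,
            "batch_remove": self.batch_remove,
        }
        if not removable:
            self.result_ = OptimizationResult(anchors, [], [], config)
            self.selected_genes_ = list(anchors)
            return self

        current = list(removable)
        err = error_of(current)
        trace = [err]
        removed = []
        while current and len(anchors) + len(current) > max(self.min_genes, len(anchors)):
            scores = [(error_of([g for g in current if g != cand]), cand) for cand in current]
            scores.sort(key=lambda t: (t[0], t[1]))  # lexicographic tie-break on gene id
            if self.batch_remove:
                drops = [cand for e, cand in scores if err - e > self.patience]
                if not drops:
                    break
                # re-verify the combined removal actually helps
                trial = [g for g in current if g not in drops]
                e_new = error_of(trial) if trial else error_of([])
                if err - e_new <= self.patience:
                    drops = [scores[0][1]]
                    e_new = scores[0][0]
                for d in drops:
                    removed.append((d, e_new))
                current = [g for g in current if g not in drops]
                err = e_new
                trace.append(err)
            else:
                e_best, cand = scores[0]
                if err - e_best <= self.patience:
                    break
                current.remove(cand)
                removed.append((cand, e_best))
                err = e_best
                trace.append(err)

        self.result_ = OptimizationResult(anchors + current, removed, trace, config)
        self.selected_genes_ = list(anchors) + current
        return self

    def transform(self, expr: ExpressionMatrix) -> ExpressionMatrix:
        return expr.subset_genes(self.selected_genes_)


def optimize_gene_set(expr: ExpressionMatrix, pool: GeneSet, k=3, v_folds=5,
                      restarts=3, seed=None, min_genes=0, patience=0.0,
                      metric="nrmse", batch_remove=False) -> OptimizationResult:
    """Functional wrapper over :class:`GeneSetOptimizer`."""
    opt = GeneSetOptimizer(k=k, v_folds=v_folds, restarts=restarts,
                           min_genes=min_genes, patience=patience, metric=metric,
                           batch_remove=batch_remove, random_state=seed)
    return opt.fit(expr, pool).result_
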