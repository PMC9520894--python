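"""Signature-based drug-response prediction and its evaluation statistics.

Binary response (venetoclax-style): a logistic model on per-sample
signature activities, evaluated by a 10x repeated 70/30 train-test scheme.
Per-sample sensitivity probabilities are averaged over the repeats in which
the sample was held out, and a pooled AUROC is computed by combining the
held-out predictions of all repeats.  Model comparisons use the two-sided
DeLong test for correlated ROC curves (structural-components variance
estimate) and its 95% confidence interval.

Continuous response (MCL1-inhibitor-style small cohorts): leave-one-out
cross-validated ordinary least squares, scored by RMSE normalized to the
observed response range (NRMSE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .io import ExpressionMatrix

__all__ = [
    "auroc",
    "delong_test",
    "delong_ci",
    "ClassifierEvaluation",
    "RegressionEvaluation",
    "RepeatedSplitClassifier",
    "repeated_split_evaluate",
    "build_comparator_features",
    "nrmse",
    "loocv_nrmse",
]


# ---------------------------------------------------------------- AUROC


def auroc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney concordance probability:
    (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------- DeLong


def _midrank(x):
    return stats.rankdata(x, method="average")


def _delong_components(scores, y):
    """Per-observation structural components V10 (positives), V01 (negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ = np.concatenate([pos, neg])
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(all_)
    theta = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return theta, v10, v01


def delong_ci(scores, labels, alpha=0.05):
    """Single-model AUROC, its DeLong variance and a normal 95% CI."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    theta, v10, v01 = _delong_components(scores, y)
    m, n = len(v10), len(v01)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return float(theta), float(var), (float(np.clip(theta - half, 0, 1)),
                                      float(np.clip(theta + half, 0, 1)))


def delong_test(scores_a, scores_b, labels):
    """Two-sided DeLong test comparing two correlated AUROCs.

    Both score vectors must be paired on the same samples.  Returns
    (auroc_a, auroc_b, z, p).  Zero variance of the difference with equal
    AUROCs gives p = 1 by convention; unequal AUROCs with zero variance is
    a degenerate input and raises.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be paired, equal-length")
    ta, v10a, v01a = _delong_components(sa, y)
    tb, v10b, v01b = _delong_components(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var_diff <= 0:
        if np.isclose(ta, tb):
            return float(ta), float(tb), 0.0, 1.0
        raise ValueError("zero variance of the AUROC difference with unequal AUROCs")
    z = (ta - tb) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(ta), float(tb), float(z), float(p)


# ------------------------------------------------- repeated-split classifier


@dataclass
class ClassifierEvaluation:
    """Pooled evaluation of the repeated 70/30 training-testing scheme."""

    sample_probability: pd.Series          # averaged held-out P(sensitive)
    pooled_auroc: float
    pooled_ci: tuple
    pooled_scores: np.ndarray              # all held-out predictions, concatenated
    pooled_labels: np.ndarray
    splits: list                           # (train_idx, test_idx) per repeat
    coefficients: list                     # fitted coefficient vector per repeat
    rank_test_p: float                     # Wilcoxon rank-sum on averaged probabilities
    comparisons: list = field(default_factory=list)

    def compare_with(self, other: "ClassifierEvaluation", name="comparator"):
        """DeLong test against another evaluation on the same pooled samples."""
        if len(self.pooled_scores) != len(other.pooled_scores) or \
                not np.array_equal(self.pooled_labels, other.pooled_labels):
            raise ValueError("evaluations are not paired on identical pooled samples")
        a_auc, b_auc, z, p = delong_test(self.pooled_scores, other.pooled_scores,
                                         self.pooled_labels)
        record = {"model_b": name, "auroc_a": a_auc, "auroc_b": b_auc, "z": z, "p": p}
        self.comparisons.append(record)
        return record


class RepeatedSplitClassifier(BaseEstimator, ClassifierMixin):
    """Ridge-stabilized logistic model evaluated by repeated stratified splits.

    Parameters
    ----------
    n_repeats : int, default 10
    train_frac : float, default 0.7
        Fraction of samples in each training split (stratified by class so
        both classes appear in every training set).
    ridge : float, default 1e-4
        L2 penalty strength on standardized features; plain logistic
        regression diverges on separable splits, so a small ridge keeps the
        fit defined everywhere.
    random_state : int or None

    Attributes
    ----------
    evaluation_ : ClassifierEvaluation   held-out evaluation over repeats
    final_model_ : sklearn Pipeline      refit on all samples
    classes_ : ndarray
    """

    def __init__(self, n_repeats=10, train_frac=0.7, ridge=1e-4, random_state=None):
        self.n_repeats = n_repeats
        self.train_frac = train_frac
        self.ridge = ridge
        self.random_state = random_state

    def _new_model(self):
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0 / max(self.ridge, 1e-12),
                               solver="lbfgs", max_iter=2000),
        )

    def fit(self, X, y):
        if isinstance(y, pd.Series):
            sample_ids = list(y.index)
        elif isinstance(X, pd.DataFrame):
            sample_ids = list(X.index)
        else:
            sample_ids = [f"S{j + 1}" for j in range(len(X))]
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        n = len(y)
        splitter = StratifiedShuffleSplit(
            n_splits=self.n_repeats, train_size=self.train_frac,
            random_state=self.random_state)
        probs = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        pooled_scores, pooled_labels, splits, coefs = [], [], [], []
        for train, test in splitter.split(X, y):
            model = self._new_model()
            model.fit(X[train], y[train])
            p = model.predict_proba(X[test])[:, 1]
            probs[test] += p
            counts[test] += 1
            pooled_scores.append(p)
            pooled_labels.append(y[test])
            splits.append((train, test))
            coefs.append(model[-1].coef_.ravel().copy())
        never = counts == 0
        if never.any():
            warnings.warn(
                f"{int(never.sum())} samples never appeared in a test split; "
                "they receive no averaged probability and are excluded"
            )
        avg = np.where(counts > 0, probs / np.maximum(counts, 1), np.nan)
        pooled_scores = np.concatenate(pooled_scores)
        pooled_labels = np.concatenate(pooled_labels)
        pauc, _, ci = delong_ci(pooled_scores, pooled_labels)
        seen = ~never
        rank_p = float(stats.mannwhitneyu(avg[seen][y[seen] == 1],
                                          avg[seen][y[seen] == 0],
                                          alternative="two-sided").pvalue)
        self.evaluation_ = ClassifierEvaluation(
            sample_probability=pd.Series(avg, index=sample_ids),
            pooled_auroc=float(pauc), pooled_ci=ci,
            pooled_scores=pooled_scores, pooled_labels=pooled_labels,
            splits=splits, coefficients=coefs, rank_test_p=rank_p,
        )
        self.final_model_ = self._new_model().fit(X, y)
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        return self.final_model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.final_model_.predict(np.asarray(X, dtype=float))


def repeated_split_evaluate(features, labels, n_repeats=10, train_frac=0.7,
                            seed=None, ridge=1e-4) -> ClassifierEvaluation:
    """Evaluate a logistic model on `features` (samples x p) by the repeated
    stratified 70/30 scheme; see :class:`RepeatedSplitClassifier`."""
    clf = RepeatedSplitClassifier(n_repeats=n_repeats, train_frac=train_frac,
                                  ridge=ridge, random_state=seed)
    if isinstance(features, pd.DataFrame):
        y = pd.Series(np.asarray(labels).astype(int), index=features.index)
        clf.fit(features.to_numpy(dtype=float), y)
    else:
        clf.fit(features, labels)
    return clf.evaluation_


# ---------------------------------------------------- comparator features


ANCHORS3 = ("BCL2", "MCL1", "BCL2A1")
ANCHORS5 = ANCHORS3 + ("BCL2L1", "BCL2L2")


def build_comparator_features(expr: ExpressionMatrix, labels=None,
                              mode: str = "anchors3", n_top: int = 10) -> pd.DataFrame:
    """Baseline feature sets the signature model is compared against.

    anchors3: expression of BCL2, MCL1, BFL1.  anchors5: plus BCLXL, BCLW.
    topN_deg: the `n_top` genes with the largest absolute difference of
    class means on the (log-scale) matrix — a fold-change ranking.
    Returns a samples x features DataFrame.
    """
    if mode in ("anchors3", "anchors5"):
        wanted = ANCHORS3 if mode == "anchors3" else ANCHORS5
        missing = [g for g in wanted if g not in expr.gene_ids]
        if missing:
            raise KeyError(f"anchor features absent from matrix: {missing}")
        sub = expr.subset_genes(wanted)
        return sub.to_frame().T
    if mode == "topN_deg":
        if labels is None:
            raise ValueError("topN_deg requires labels")
        y = np.asarray(labels).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present for DEG ranking")
        diff = np.abs(expr.values[:, y == 1].mean(axis=1) -
                      expr.values[:, y == 0].mean(axis=1))
        if n_top > expr.n_genes:
            warnings.warn(f"n_top={n_top} exceeds gene count {expr.n_genes}; using all")
            n_top = expr.n_genes
        order = np.lexsort((np.array(expr.gene_ids), -diff))  # ties: gene id
        top = [expr.gene_ids[i] for i in order[:n_top]]
        return expr.subset_genes(top).to_frame().T
    raise ValueError(f"unknown comparator mode {mode!r}")


# ----------------------------------------------------------- LOOCV NRMSE


def nrmse(predictions, observed) -> float:
    """Root-mean-square error normalized by the observed range."""
    predictions = np.asarray(predictions, dtype=float)
    observed = np.asarray(observed, dtype=float)
    rng_y = observed.max() - observed.min()
    if rng_y <= 0:
        raise ValueError("zero response range; NRMSE undefined")
    return float(np.sqrt(np.mean((predictions - observed) ** 2)) / rng_y)


@dataclass
class RegressionEvaluation:
    predictions: pd.Series        # one held-out prediction per sample
    observed: pd.Series
    nrmse: float
    model: str = "OLS-LOOCV"


def loocv_nrmse(features, response) -> RegressionEvaluation:
    """Leave-one-out OLS prediction of a continuous response, scored by
    RMSE normalized to the observed response range."""
    if isinstance(features, pd.DataFrame):
        ids = list(features.index)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        ids = [f"S{j + 1}" for j in range(len(X))]
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"n={n} too small for p={p} features (need n >= p + 2)")
    rng_y = y.max() - y.min()
    if rng_y <= 0:
        raise ValueError("zero response range; NRMSE undefined")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = LinearRegression().fit(X[keep], y[keep])
        preds[i] = model.predict(X[i:i + 1])[0]
    return RegressionEvaluation(pd.Series(preds, index=ids),
                                pd.Series(y, index=ids), nrmse(preds, y))
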