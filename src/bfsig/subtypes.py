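"""Signature-based subtyping and the group-comparison statistics used with it.

Samples are clustered on their signature-activity profiles (columns of H)
by average-linkage hierarchical clustering under Pearson-correlation
distance, the dendrogram is cut into `n_clusters` groups, and each cluster
is named after the signature with the highest mean activity inside it —
yielding subtypes such as "BCL2", "MCL1/BCL2" and "BFL1/MCL1".

Thin wrappers over scipy provide the accompanying statistics: Welch's
t-test for signature differences between response groups, a Pearson
chi-square for subtype proportions across datasets, and Kruskal-Wallis /
Wilcoxon rank-sum tests for drug-response screening across subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .io import ResponseTable
from .signatures import SignatureSet

__all__ = [
    "SubtypeAssignment",
    "cluster_samples",
    "compare_signatures_between_groups",
    "subtype_proportion_test",
    "drug_screen_by_subtype",
    "spearman_rho",
]


@dataclass
class SubtypeAssignment:
    assignments: pd.DataFrame     # index sample_id; columns cluster, label
    linkage: np.ndarray
    n_clusters: int

    def labels_for(self, sample_ids):
        return self.assignments.loc[list(sample_ids), "label"].tolist()

    def save(self, path):
        self.assignments.to_csv(path, sep="\t", index_label="sample_id")


def _correlation_distance(X):
    """1 - Pearson r between rows of X; zero-variance rows handled by caller."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    denom = np.outer(norm, norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ Xc.T) / denom
    return 1.0 - np.clip(corr, -1.0, 1.0)


def cluster_samples(H, n_clusters: int = 3, signature_labels=None) -> SubtypeAssignment:
    """Cut an average-linkage dendrogram of 1 - Pearson sample distances.

    `H` is a signatures x samples activity matrix (DataFrame preferred so
    sample/signature names carry through).  Each cluster is labeled by the
    signature with the highest mean activity among its samples.  Samples
    whose activity vector has zero variance (correlation undefined) are
    assigned to the cluster of their nearest Euclidean neighbor, with a
    warning.
    """
    if isinstance(H, SignatureSet):
        H = H.H
    if isinstance(H, pd.DataFrame):
        sig_names = list(H.index)
        sample_ids = list(H.columns)
        X = H.to_numpy(dtype=float).T
    else:
        X = np.asarray(H, dtype=float).T
        sig_names = signature_labels or [f"sig_{i + 1}" for i in range(X.shape[1])]
        sample_ids = [f"S{j + 1}" for j in range(X.shape[0])]
    if signature_labels is not None:
        sig_names = list(signature_labels)
    n = X.shape[0]
    if n < n_clusters:
        raise ValueError(f"{n} samples cannot form {n_clusters} clusters")

    flat = X.std(axis=1) == 0
    ok = ~flat
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance sample vectors assigned by nearest neighbor"
        )
    D = _correlation_distance(X[ok])
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    clusters_ok = fcluster(Z, t=n_clusters, criterion="maxclust")
    clusters = np.empty(n, dtype=int)
    clusters[ok] = clusters_ok
    if flat.any():
        ok_idx = np.flatnonzero(ok)
        for j in np.flatnonzero(flat):
            d = ((X[ok] - X[j]) ** 2).sum(axis=1)
            clusters[j] = clusters[ok_idx[np.argmin(d)]]

    label_of = {}
    for c in np.unique(clusters):
        mean_act = X[clusters == c].mean(axis=0)
        label_of[c] = sig_names[int(np.argmax(mean_act))]
    frame = pd.DataFrame(
        {"cluster": clusters, "label": [label_of[c] for c in clusters]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SubtypeAssignment(frame, Z, int(len(np.unique(clusters))))


def compare_signatures_between_groups(H, groups) -> pd.DataFrame:
    """Welch's unequal-variance t-test per signature between two groups.

    `groups` is a boolean/binary vector over samples; returns a DataFrame
    with t, Welch-Satterthwaite df and two-sided p per signature.
    """
    if isinstance(H, pd.DataFrame):
        sig_names = list(H.index)
        X = H.to_numpy(dtype=float)
    else:
        X = np.asarray(H, dtype=float)
        sig_names = [f"sig_{i + 1}" for i in range(X.shape[0])]
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    g1, g2 = (groups == uniq[0]), (groups == uniq[1])
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    rows = []
    for i, name in enumerate(sig_names):
        a, b = X[i, g1], X[i, g2]
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append((name, float(res.statistic), float(res.df), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["signature", "t", "df", "p"]).set_index("signature")


def subtype_proportion_test(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a subtype x dataset table."""
    table = np.asarray(counts, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def drug_screen_by_subtype(responses: ResponseTable, assignment: SubtypeAssignment,
                           value: str = "auc", fdr: bool = False) -> pd.DataFrame:
    """Per-drug Kruskal-Wallis across subtypes plus pairwise Wilcoxon rank-sum.

    Rank-sum p-values use the exact null distribution where sample sizes
    permit (scipy's Mann-Whitney with its automatic exact/asymptotic
    switch).  Raw p-values are reported; `fdr=True` adds
    Benjamini-Hochberg-adjusted columns.
    """
    df = responses.data
    rows = []
    for drug, sub in df.groupby("drug"):
        sub = sub[sub["sample_id"].isin(assignment.assignments.index)]
        labels = assignment.assignments.loc[sub["sample_id"], "label"].to_numpy()
        vals = sub[value].to_numpy(dtype=float)
        keep = ~np.isnan(vals)
        vals, labels = vals[keep], labels[keep]
        grp_names = [g for g in pd.unique(labels) if (labels == g).sum() >= 2]
        if len(grp_names) < 2:
            warnings.warn(f"drug {drug!r}: fewer than two subtypes with >= 2 samples")
            continue
        groups = [vals[labels == g] for g in grp_names]
        if np.ptp(np.concatenate(groups)) == 0:
            kw_p = 1.0  # all responses tied; nothing to rank
        else:
            kw_p = float(stats.kruskal(*groups).pvalue)
        pairs = {}
        for i in range(len(grp_names)):
            for j in range(i + 1, len(grp_names)):
                both = np.concatenate([groups[i], groups[j]])
                if np.ptp(both) == 0:
                    pairs[f"{grp_names[i]}|{grp_names[j]}"] = 1.0
                    continue
                res = stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
                pairs[f"{grp_names[i]}|{grp_names[j]}"] = float(res.pvalue)
        rows.append({"drug": drug, "kruskal_p": kw_p, **{f"wilcoxon_{k}": v
                                                         for k, v in pairs.items()}})
    out = pd.DataFrame(rows).set_index("drug") if rows else pd.DataFrame()
    if fdr and not out.empty:
        from statsmodels.stats.multitest import multipletests

        for col in out.columns:
            vals = out[col].to_numpy(dtype=float)
            out[col + "_bh"] = multipletests(vals, method="fdr_bh")[1]
    return out


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with midranked ties."""
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
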