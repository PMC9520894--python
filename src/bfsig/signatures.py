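"""Signature extraction: consensus-based NMF rank selection, weight
normalization, anchor-based labeling and cross-dataset concordance.

Rank selection follows standard NMF consensus-clustering practice: for each
candidate rank, NMF is re-fit from many seeded initializations; each run's
H matrix yields a binary connectivity matrix (samples co-assigned iff they
share the same dominant factor), the run-averaged consensus matrix measures
clustering stability, and the cophenetic correlation coefficient of the
consensus summarizes it.  The chosen rank is the one at which the
cophenetic coefficient "begins to fall" — the smallest k whose coefficient
drops by more than `drop_tol` going to k+1.

Extracted signatures have gene weights normalized to sum to one per
signature (H rescaled inversely, so the reconstruction is unchanged), and
are labeled by which anchor gene dominates them, e.g. BCL2, MCL1/BCL2 or
BFL1/MCL1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .io import DEFAULT_ANCHORS, ExpressionMatrix
from .nmf import fit_masked_nmf

__all__ = [
    "SignatureSet",
    "RankSelectionReport",
    "connectivity_matrix",
    "consensus_and_cophenetic",
    "select_rank",
    "extract_signatures",
    "label_signatures",
    "signature_concordance",
]


@dataclass
class SignatureSet:
    """Labeled, weight-normalized NMF signatures with per-sample activities.

    W_norm columns each sum to one; H is rescaled so W_norm @ H equals the
    original reconstruction.
    """

    W_norm: pd.DataFrame          # genes x signatures
    H: pd.DataFrame               # signatures x samples
    labels: list                  # per-signature label, unique
    rank: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        sums = self.W_norm.to_numpy().sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"W_norm columns must sum to 1; got {sums}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"signature labels must be unique: {self.labels}")

    def relabel(self, labels):
        w = self.W_norm.copy()
        h = self.H.copy()
        w.columns = labels
        h.index = labels
        return SignatureSet(w, h, list(labels), self.rank, self.provenance)

    def save(self, outdir):
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.W_norm.to_csv(outdir / "W_norm.tsv", sep="\t")
        self.H.to_csv(outdir / "H.tsv", sep="\t")
        with open(outdir / "labels.json", "w") as fh:
            json.dump({"labels": self.labels, "rank": self.rank,
                       "provenance": self.provenance}, fh, indent=2)


@dataclass
class RankSelectionReport:
    ranks: list
    cophenetic: dict               # rank -> coefficient
    consensus: dict                # rank -> n x n consensus matrix
    chosen_rank: int
    n_runs: int
    seed: int | None

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"ranks": list(self.ranks),
                       "cophenetic": {str(k): v for k, v in self.cophenetic.items()},
                       "chosen_rank": self.chosen_rank,
                       "n_runs": self.n_runs, "seed": self.seed}, fh, indent=2)


def connectivity_matrix(H, normalize: bool = False) -> np.ndarray:
    """Binary co-clustering matrix: C[i,j] = 1 iff samples i and j share the
    same dominant (argmax) signature.  Ties resolve to the lowest index.

    With ``normalize=True`` each factor's activity row is divided by its
    mean before the argmax, so the assignment is invariant to the arbitrary
    per-factor scaling of an NMF fit (a small extra factor can still claim
    the samples where it is relatively strongest).
    """
    H = np.asarray(H, dtype=float)
    if normalize:
        H = H / np.maximum(H.mean(axis=1, keepdims=True), 1e-12)
    if H.shape[0] < 2:
        raise ValueError("connectivity needs k >= 2")
    dead = ~np.any(H > 0, axis=0)
    if dead.any():
        raise ValueError(
            f"samples with all-zero activities, assignment undefined: "
            f"{np.flatnonzero(dead).tolist()}"
        )
    assign = np.argmax(H, axis=0)
    return (assign[:, None] == assign[None, :]).astype(float)


def _cophenetic_of_consensus(consensus):
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.ptp(condensed) == 0:
        binary = np.isin(np.unique(consensus), (0.0, 1.0)).all()
        if binary:
            return 1.0
        raise ValueError("degenerate consensus: all pairwise distances identical")
    Z = linkage(condensed, method="average")
    c, _ = cophenet(Z, condensed)
    if np.isnan(c):
        binary = np.isin(np.unique(consensus), (0.0, 1.0)).all()
        if binary:
            return 1.0
        raise ValueError("degenerate consensus: cophenetic correlation undefined")
    return float(c)


def consensus_and_cophenetic(A, k, n_runs=20, seed=None, max_iter=2000, tol=1e-6):
    """Consensus matrix and cophenetic coefficient for one candidate rank.

    Runs `n_runs` seeded single-restart NMF fits, averages their
    connectivity matrices, and correlates the consensus-derived distances
    (1 - consensus) with the cophenetic distances of their average-linkage
    dendrogram.  A perfectly block-structured binary consensus scores 1.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    values = A.values if isinstance(A, ExpressionMatrix) else np.asarray(A, dtype=float)
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    n = values.shape[1]
    consensus = np.zeros((n, n))
    for s in run_seeds:
        model = fit_masked_nmf(values, k, seed=int(s), max_iter=max_iter,
                               tol=tol, n_restarts=1)
        consensus += connectivity_matrix(model.H_, normalize=True)
    consensus /= n_runs
    return consensus, _cophenetic_of_consensus(consensus)


def select_rank(A, ranks=range(2, 7), n_runs=20, seed=None, drop_tol=0.001,
                max_iter=2000, tol=1e-6) -> RankSelectionReport:
    """Choose the NMF rank at which clustering stability begins to fall.

    The chosen rank is the smallest k in `ranks` with
    coph(k) - coph(k+1) > drop_tol; if the coefficient never falls that
    much, the largest rank is returned with a warning.

    The default tolerance is calibrated to sit between the run-to-run
    jitter of the coefficient at `n_runs` = 20 (well below 1e-3) and the
    smallest genuine stability losses observed past the true rank; the
    coefficient's useful dynamic range under argmax consensus is narrow
    (roughly 0.94-1.0), so a much larger tolerance misses real falls.
    """
    ranks = list(ranks)
    if len(ranks) < 2:
        raise ValueError("need at least two candidate ranks")
    if sorted(ranks) != list(range(min(ranks), max(ranks) + 1)) or min(ranks) < 2:
        raise ValueError("ranks must be a contiguous range with minimum >= 2")
    coph, cons = {}, {}
    for k in ranks:
        cons[k], coph[k] = consensus_and_cophenetic(A, k, n_runs=n_runs, seed=seed,
                                                    max_iter=max_iter, tol=tol)
    chosen = None
    for k in ranks[:-1]:
        if coph[k] - coph[k + 1] > drop_tol:
            chosen = k
            break
    if chosen is None:
        chosen = max(ranks)
        warnings.warn(
            f"cophenetic coefficient never fell by more than {drop_tol}; "
            f"defaulting to the largest rank {chosen}"
        )
    return RankSelectionReport(ranks, coph, cons, chosen, n_runs, seed)


def extract_signatures(A_opt: ExpressionMatrix, k, restarts=5, seed=None,
                       max_iter=2000, tol=1e-6) -> SignatureSet:
    """Best-of-restarts NMF fit with sum-to-one weight normalization.

    Each signature's gene weights are scaled to sum to 1 and the matching
    H row is scaled inversely, leaving W_norm @ H identical to the raw
    reconstruction.  Labels are generic until :func:`label_signatures`.
    """
    model = fit_masked_nmf(A_opt.values, k, seed=seed, max_iter=max_iter,
                           tol=tol, n_restarts=restarts)
    W, H = model.W_, model.H_
    colsums = W.sum(axis=0)
    if np.any(colsums <= 0):
        raise ValueError(f"degenerate all-zero signature column(s): "
                         f"{np.flatnonzero(colsums <= 0).tolist()}")
    W_norm = W / colsums
    H_scaled = H * colsums[:, None]
    sig_names = [f"sig_{i + 1}" for i in range(k)]
    return SignatureSet(
        W_norm=pd.DataFrame(W_norm, index=list(A_opt.gene_ids), columns=sig_names),
        H=pd.DataFrame(H_scaled, index=sig_names, columns=list(A_opt.sample_ids)),
        labels=sig_names,
        rank=k,
        provenance={"seed": seed, "restarts": restarts,
                    "final_loss": model.reconstruction_err_},
    )


_SHORT = {"BCL2A1": "BFL1", "BCL2L1": "BCLXL", "BCL2L2": "BCLW"}


def label_signatures(sigs: SignatureSet, anchors=DEFAULT_ANCHORS,
                     composite_ratio=0.5) -> SignatureSet:
    """Name each signature after the anchor gene(s) dominating it.

    Primary names are drawn from the leading anchors (the resistance-factor
    trio BCL2, MCL1, BFL1 when the default anchor order is used): each
    anchor's weights are normalized across signatures (its profile) and the
    first min(k, #present) anchors are matched one-to-one to signatures by
    maximum-total-profile-weight bipartite assignment, keeping labels
    unique.  When another anchor's profile on a signature reaches
    `composite_ratio` of the primary's, a composite label such as
    "MCL1/BCL2" is used.  Without any anchor present, generic sig_i labels
    are kept with a warning.
    """
    present = [a for a in anchors if a in sigs.W_norm.index]
    if not present:
        warnings.warn("no anchors among signature genes; keeping generic labels")
        return sigs
    k = sigs.rank
    prof_all = sigs.W_norm.loc[present].to_numpy()
    rowsum = prof_all.sum(axis=1, keepdims=True)
    prof_all = np.divide(prof_all, rowsum, out=np.zeros_like(prof_all),
                         where=rowsum > 0)
    primary_pool = present[:min(k, len(present))]
    prof = prof_all[: len(primary_pool)]
    # assignment: signature x primary-anchor, maximize total profile weight
    cost = -prof.T
    if len(primary_pool) < k:
        pad = np.zeros((k, k - len(primary_pool)))
        cost = np.hstack([cost, pad])
    rows, cols = linear_sum_assignment(cost)
    labels = []
    for sig_idx, anch_idx in sorted(zip(rows, cols)):
        if anch_idx >= len(primary_pool):
            labels.append(f"sig_{sig_idx + 1}")
            continue
        primary = primary_pool[anch_idx]
        others = [(prof_all[a, sig_idx], present[a]) for a in range(len(present))
                  if present[a] != primary]
        others.sort(reverse=True)
        name = _SHORT.get(primary, primary)
        if others and prof[anch_idx, sig_idx] > 0 and \
                others[0][0] >= composite_ratio * prof[anch_idx, sig_idx]:
            second = _SHORT.get(others[0][1], others[0][1])
            if second != name:
                name = f"{name}/{second}"
        labels.append(name)
    if len(set(labels)) != len(labels):  # composite collisions: disambiguate
        seen, unique = {}, []
        for lb in labels:
            if lb in seen:
                seen[lb] += 1
                unique.append(f"{lb}#{seen[lb]}")
            else:
                seen[lb] = 1
                unique.append(lb)
        labels = unique
    return sigs.relabel(labels)


def signature_concordance(W1: pd.DataFrame, W2: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of gene weights between two signature sets.

    Computed over the intersection of gene identifiers (at least 5 genes),
    with midranked ties, for every pair of signatures.
    """
    shared = W1.index.intersection(W2.index)
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared genes; need >= 5")
    out = pd.DataFrame(index=W1.columns, columns=W2.columns, dtype=float)
    for c1 in W1.columns:
        for c2 in W2.columns:
            rho, _ = spearmanr(W1.loc[shared, c1], W2.loc[shared, c2])
            out.loc[c1, c2] = rho
    return out
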