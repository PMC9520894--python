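"""Data containers and file I/O for expression matrices, gene sets and drug response.

Expression matrices are genes-in-rows tables (TSV/CSV, header row of sample
identifiers), the orientation bulk-RNA-seq pipelines conventionally emit.
Gene sets are GMT lines or one-symbol-per-line lists.  Drug response is a
long table with one row per (sample, drug) measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "ResponseTable",
    "DEFAULT_ANCHORS",
    "load_expression_matrix",
    "load_gene_set",
    "load_response_table",
    "binarize_response",
    "deduplicate_by_latest_timepoint",
    "log2_transform",
]

#: The five anti-apoptotic BCL2-family genes whose profiles anchor the
#: gene-optimization step: BCL2, MCL1, BFL1 (BCL2A1), BCLXL (BCL2L1),
#: BCLW (BCL2L2).
DEFAULT_ANCHORS = ("BCL2", "MCL1", "BCL2A1", "BCL2L1", "BCL2L2")


class IdentifierError(ValueError):
    """Duplicate or inconsistent gene/sample identifiers."""


class DomainError(ValueError):
    """Values outside the domain the model requires (e.g. negative expression)."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated non-negative gene x sample expression matrix.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Non-negative, finite expression values (any units; typically
        log-scale normalized counts).
    gene_ids : sequence of unique str
    sample_ids : sequence of unique str
    """

    values: np.ndarray
    gene_ids: tuple
    sample_ids: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        g, n = values.shape
        if len(self.gene_ids) != g or len(self.sample_ids) != n:
            raise IdentifierError(
                f"identifier lengths ({len(self.gene_ids)}, {len(self.sample_ids)}) "
                f"do not match matrix shape {values.shape}"
            )
        if len(set(self.gene_ids)) != g:
            dupes = _duplicates(self.gene_ids)
            raise IdentifierError(f"duplicate gene identifiers: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise IdentifierError(f"duplicate sample identifiers: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DomainError(
                f"non-finite expression at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise DomainError(
                f"negative expression {values[i, j]} at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of `genes`, raising KeyError for absent identifiers."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(self.values[idx], [self.gene_ids[i] for i in idx], self.sample_ids)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        idx = [lookup[s] for s in samples]
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, [self.sample_ids[j] for j in idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), frame.index.astype(str), frame.columns.astype(str))

    def save(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


def _duplicates(ids):
    seen, dup = set(), set()
    for x in ids:
        (dup if x in seen else seen).add(x)
    return dup


@dataclass(frozen=True)
class GeneSet:
    """A curated set of gene identifiers with a designated anchor subset.

    Anchors are the genes whose expression the imputation-guided optimization
    must reconstruct; they default to the five anti-apoptotic BCL2-family
    members and are never removable.
    """

    members: frozenset
    anchors: tuple

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))
        object.__setattr__(self, "anchors", tuple(str(a) for a in self.anchors))
        if not self.members:
            raise DomainError("gene set has no members")
        if not self.anchors:
            raise DomainError("anchor list is empty")
        if len(set(self.anchors)) != len(self.anchors):
            raise IdentifierError("duplicate anchors")
        if not set(self.anchors) <= self.members:
            raise IdentifierError(
                f"anchors not contained in members: {sorted(set(self.anchors) - self.members)}"
            )

    def __len__(self) -> int:
        return len(self.members)

    def non_anchor_members(self):
        return sorted(self.members - set(self.anchors))


@dataclass
class ResponseTable:
    """Per-sample drug measurements with patient/time-point lineage.

    Wraps a DataFrame with columns ``sample_id, patient_id, time_point,
    drug, ic50_uM, auc`` and (after :func:`binarize_response`)
    ``binary_class`` in {"sensitive", "resistant", "excluded"}.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample_id", "patient_id", "time_point", "drug")

    def __post_init__(self):
        df = self.data.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise IdentifierError(f"response table missing column {col!r}")
        for col in ("ic50_uM", "auc"):
            if col not in df.columns:
                df[col] = np.nan
        if df.duplicated(["sample_id", "drug"]).any():
            bad = df.loc[df.duplicated(["sample_id", "drug"]), ["sample_id", "drug"]]
            raise IdentifierError(f"duplicate (sample_id, drug) rows: {bad.values[:5].tolist()}")
        both_missing = df["ic50_uM"].isna() & df["auc"].isna()
        if both_missing.any():
            raise DomainError(
                f"rows with neither ic50_uM nor auc: {df.loc[both_missing, 'sample_id'].tolist()[:5]}"
            )
        if (df["ic50_uM"].dropna() <= 0).any():
            raise DomainError("ic50_uM must be positive")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def for_drug(self, drug: str) -> "ResponseTable":
        return ResponseTable(self.data[self.data["drug"] == drug])

    def save(self, path, delimiter: str = "\t") -> None:
        self.data.to_csv(path, sep=delimiter, index=False)


def load_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples expression table.

    First row holds sample identifiers, first column gene identifiers;
    the body must be numeric and non-negative.
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    body = frame.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any() and not frame.isna().any().any():
        i, j = np.argwhere(body.isna().to_numpy())[0]
        raise DomainError(
            f"non-numeric value {frame.iloc[i, j]!r} at gene {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}"
        )
    return ExpressionMatrix.from_frame(body)


def load_gene_set(
    path,
    format: str = "list",
    anchors=DEFAULT_ANCHORS,
    expression: ExpressionMatrix | None = None,
) -> GeneSet:
    """Read a gene set from a GMT file (first line used) or a plain list.

    When an `expression` matrix is supplied, members absent from it are
    reported with a warning (exact, case-sensitive identifier matching).
    """
    members: list[str] = []
    with open(path) as fh:
        if format == "gmt":
            line = fh.readline().rstrip("\n")
            fields = line.split("\t")
            if len(fields) < 3:
                raise DomainError(f"malformed GMT line in {path}")
            members = [f for f in fields[2:] if f]
        elif format == "list":
            members = [ln.strip() for ln in fh if ln.strip()]
        else:
            raise ValueError(f"unknown gene-set format {format!r}")
    members = list(dict.fromkeys(members))
    if not members:
        raise DomainError(f"empty gene set in {path}")
    anchors = tuple(a for a in anchors if a in members) or tuple(anchors)
    gs = GeneSet(frozenset(members) | set(anchors), anchors)
    if expression is not None:
        absent = sorted(gs.members - set(expression.gene_ids))
        if absent:
            warnings.warn(f"{len(absent)} gene-set members absent from expression matrix: {absent[:10]}")
    return gs


def save_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene_set.members):
            fh.write(g + "\n")


def load_response_table(path, delimiter: str = "\t") -> ResponseTable:
    return ResponseTable(pd.read_csv(path, sep=delimiter))


def binarize_response(
    table: ResponseTable,
    drug: str,
    sensitive_max: float = 1.0,
    resistant_min: float = 10.0,
) -> ResponseTable:
    """Binarize IC50 into response classes.

    Samples are sensitive if IC50 <= `sensitive_max` uM and resistant if
    IC50 >= `resistant_min` uM (both boundaries inclusive); values strictly
    between the thresholds are labeled ``excluded``.
    """
    if sensitive_max >= resistant_min:
        raise ValueError(
            f"sensitive_max ({sensitive_max}) must be < resistant_min ({resistant_min})"
        )
    df = table.for_drug(drug).data.copy()
    if df.empty:
        raise DomainError(f"no rows for drug {drug!r}")
    if df["ic50_uM"].isna().any():
        bad = df.loc[df["ic50_uM"].isna(), "sample_id"].tolist()
        raise DomainError(f"missing ic50_uM for drug {drug!r}: {bad[:5]}")
    ic50 = df["ic50_uM"].to_numpy(dtype=float)
    cls = np.where(ic50 <= sensitive_max, "sensitive",
                   np.where(ic50 >= resistant_min, "resistant", "excluded"))
    df["binary_class"] = cls
    return ResponseTable(df)


def deduplicate_by_latest_timepoint(table: ResponseTable) -> ResponseTable:
    """Keep only the latest-time-point sample per (patient, response class).

    Multiple samples of one patient falling in the *same* response group are
    collapsed to the most recent one; samples of the same patient in
    *different* groups are all kept.  Ties at the maximal time point are
    ambiguous and raised as errors.
    """
    df = table.data
    if "binary_class" not in df.columns:
        raise DomainError("binary_class not assigned; run binarize_response first")
    keep_idx = []
    for (_, _), grp in df.groupby(["patient_id", "binary_class"], sort=False):
        tmax = grp["time_point"].max()
        at_max = grp[grp["time_point"] == tmax]
        if len(at_max) > 1:
            raise DomainError(
                "tied maximal time points within a patient/response group: "
                f"{at_max['sample_id'].tolist()}"
            )
        keep_idx.append(at_max.index[0])
    return ResponseTable(df.loc[sorted(keep_idx)])


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Optional log2(x + pseudocount) transform, floored at zero."""
    vals = np.maximum(np.log2(expr.values + pseudocount), 0.0)
    return ExpressionMatrix(vals, expr.gene_ids, expr.sample_ids)
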