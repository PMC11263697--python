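"""Domain types and delimited-text IO for expression assessment.

Every table the pipeline touches is tab-separated text with a header row:
expression matrices (genes x samples, gene ids in the first column), sample
sheets (library_id, lab_id, sample_type, replicate, then one column per
experimental factor), gene annotations, truth sets, and DEG call tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ContractError",
    "SCALES",
    "SAMPLE_TYPES",
    "QUARTET_TYPES",
    "MIXTURE_TYPES",
    "MAQC_TYPES",
    "LOG2_OFFSET",
    "ExpressionMatrix",
    "SampleSheet",
    "GeneAnnotation",
    "TruthSet",
    "DegCallTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_truth_set",
    "write_truth_set",
    "read_deg_calls",
    "write_deg_calls",
    "to_log2",
    "relative_expression",
]


class FormatError(ValueError):
    """A delimited input file violates the expected format."""


class ContractError(ValueError):
    """An operation was called with arguments violating its contract."""


SCALES = frozenset({"counts", "fpkm", "log2fpkm", "cpm", "tpm", "normalized"})
#: linear, non-negative scales (counts additionally integral)
_LINEAR_SCALES = frozenset({"counts", "fpkm", "cpm", "tpm"})

QUARTET_TYPES = ("M8", "F7", "D5", "D6")
MIXTURE_TYPES = ("T1", "T2")
MAQC_TYPES = ("MAQC_A", "MAQC_B")
SAMPLE_TYPES = QUARTET_TYPES + MIXTURE_TYPES + MAQC_TYPES

#: pseudo-count added to FPKM before log2 to avoid -inf
LOG2_OFFSET = 0.01

DEG_LABELS = ("up", "down", "non_de", "unassessed")
CALL_LABELS = ("up", "down", "not_de")


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric table with a declared value scale.

    ``data`` has gene ids as the index and sample (library) ids as columns.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ContractError(f"unknown scale {self.scale!r}; expected one of {sorted(SCALES)}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self.data.columns[
                [not pd.api.types.is_numeric_dtype(t) for t in self.data.dtypes]
            ].tolist()
            raise FormatError(f"non-numeric expression columns: {bad}")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        if self.scale in _LINEAR_SCALES and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value on scale {self.scale!r} at gene "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        if self.scale == "counts" and not np.allclose(values, np.round(values)):
            raise FormatError("counts must be integral")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            df = df.loc[list(genes)]
        if samples is not None:
            df = df[list(samples)]
        return ExpressionMatrix(df.copy(), self.scale)


_SHEET_COLUMNS = ["library_id", "lab_id", "sample_type", "replicate"]


@dataclass
class SampleSheet:
    """Per-library metadata: lab, sample type, replicate and factor levels."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        _check_unique(self.data["library_id"], "library ids")
        key = self.data[["lab_id", "sample_type", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate (lab_id, sample_type, replicate): {dup}")
        bad = set(self.data["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise FormatError(f"unknown sample types: {sorted(bad)}")
        if (self.data["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive")
        self.data = self.data.reset_index(drop=True)

    @property
    def factor_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in _SHEET_COLUMNS]

    @property
    def labs(self) -> list:
        return sorted(self.data["lab_id"].unique().tolist())

    def libraries(self, lab_id=None, sample_type=None, sample_types=None) -> list:
        """Library ids matching the given lab and/or sample type(s)."""
        mask = pd.Series(True, index=self.data.index)
        if lab_id is not None:
            mask &= self.data["lab_id"] == lab_id
        if sample_type is not None:
            mask &= self.data["sample_type"] == sample_type
        if sample_types is not None:
            mask &= self.data["sample_type"].isin(list(sample_types))
        return self.data.loc[mask, "library_id"].tolist()

    def sample_type_of(self) -> pd.Series:
        """Map library_id -> sample_type."""
        return self.data.set_index("library_id")["sample_type"]

    def subset(self, library_ids) -> "SampleSheet":
        ids = set(library_ids)
        return SampleSheet(self.data[self.data["library_id"].isin(ids)].copy())


@dataclass
class GeneAnnotation:
    """Per-gene length (bp), gene type and optional GC fraction."""

    data: pd.DataFrame  # index gene_id; columns length_bp, gene_type, [gc_fraction]

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        if "length_bp" not in self.data.columns:
            raise FormatError("gene annotation missing length_bp column")
        if (self.data["length_bp"] < 1).any():
            raise FormatError("gene lengths must be >= 1 bp")
        if "gc_fraction" in self.data.columns:
            gc = self.data["gc_fraction"].dropna()
            if ((gc < 0) | (gc > 1)).any():
                raise FormatError("gc_fraction must lie in [0, 1]")

    def lengths(self, gene_ids) -> pd.Series:
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise ContractError(f"genes without annotated length: {missing[:10]}")
        return self.data["length_bp"].loc[list(gene_ids)].astype(float)


@dataclass
class TruthSet:
    """Per-gene expected log2 fold change and DEG label for one comparison."""

    comparison: str  # "<numerator>/<denominator>", e.g. "M8/D6"
    data: pd.DataFrame  # index gene_id; columns expected_log2fc, deg_label

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        bad = set(self.data["deg_label"]) - set(DEG_LABELS)
        if bad:
            raise FormatError(f"unknown DEG labels: {sorted(bad)}")
        up = self.data["deg_label"] == "up"
        down = self.data["deg_label"] == "down"
        if (self.data.loc[up, "expected_log2fc"] <= 0).any():
            raise FormatError("label 'up' requires expected_log2fc > 0")
        if (self.data.loc[down, "expected_log2fc"] >= 0).any():
            raise FormatError("label 'down' requires expected_log2fc < 0")

    @property
    def numerator(self) -> str:
        return self.comparison.split("/")[0]

    @property
    def denominator(self) -> str:
        return self.comparison.split("/")[1]

    @property
    def n_deg(self) -> int:
        return int(self.data["deg_label"].isin(["up", "down"]).sum())


@dataclass
class DegCallTable:
    """Submitted differential-expression calls for one comparison.

    Genes absent from the table are interpreted as "not reported".
    """

    comparison: str
    data: pd.DataFrame  # index gene_id; columns log2fc, p, [q], call

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        bad = set(self.data["call"]) - set(CALL_LABELS)
        if bad:
            raise FormatError(f"unknown call labels: {sorted(bad)}")
        p = self.data["p"].to_numpy(float)
        if not np.all(np.isfinite(p)) or (p < 0).any() or (p > 1).any():
            raise FormatError("p-values must be finite and in [0, 1]")


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=0)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_expression_matrix(path, scale: str) -> ExpressionMatrix:
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"non-numeric cell in column {col!r}, gene {bad.index[0]!r}: {bad.iloc[0]!r}"
            )
    return ExpressionMatrix(df, scale)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(_read_tsv(path))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> GeneAnnotation:
    return GeneAnnotation(_read_tsv(path).set_index("gene_id"))


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    ann.data.to_csv(path, sep="\t", index_label="gene_id")


def read_truth_set(path, comparison: str | None = None) -> TruthSet:
    df = _read_tsv(path)
    if comparison is None:
        if "comparison" not in df.columns:
            raise FormatError("truth table without 'comparison' column needs an explicit label")
        labels = df["comparison"].unique()
        if len(labels) != 1:
            raise FormatError(f"truth table mixes comparisons: {labels.tolist()}")
        comparison = labels[0]
    df = df.drop(columns=["comparison"], errors="ignore").set_index("gene_id")
    return TruthSet(comparison, df)


def write_truth_set(truth: TruthSet, path) -> None:
    df = truth.data.copy()
    df.insert(0, "comparison", truth.comparison)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_deg_calls(path, comparison: str | None = None) -> DegCallTable:
    df = _read_tsv(path)
    if comparison is None:
        labels = df.get("comparison")
        if labels is None or labels.nunique() != 1:
            raise FormatError("DEG call table needs a single comparison label")
        comparison = labels.iloc[0]
    df = df.drop(columns=["comparison"], errors="ignore").set_index("gene_id")
    return DegCallTable(comparison, df)


def write_deg_calls(calls: DegCallTable, path) -> None:
    df = calls.data.copy()
    df.insert(0, "comparison", calls.comparison)
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# scale transforms


def to_log2(matrix: ExpressionMatrix, offset: float = LOG2_OFFSET) -> ExpressionMatrix:
    """log2(FPKM + offset); the offset avoids -inf for unexpressed genes."""
    if matrix.scale != "fpkm":
        raise ContractError(f"to_log2 expects scale 'fpkm', got {matrix.scale!r}")
    return ExpressionMatrix(np.log2(matrix.data + offset), "log2fpkm")


def relative_expression(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    reference_type: str = "D6",
) -> ExpressionMatrix:
    """Center each gene on the mean of the reference sample's replicates, per lab.

    Within every laboratory, the mean over that lab's ``reference_type``
    replicates is subtracted gene-by-gene from all of the lab's samples
    (including the reference replicates themselves, whose mean becomes 0).
    """
    if matrix.scale != "log2fpkm":
        raise ContractError(f"relative_expression expects 'log2fpkm', got {matrix.scale!r}")
    out = matrix.data.copy()
    present = set(matrix.sample_ids)
    for lab in sheet.labs:
        lab_libs = [s for s in sheet.libraries(lab_id=lab) if s in present]
        if not lab_libs:
            continue
        ref_libs = [s for s in sheet.libraries(lab_id=lab, sample_type=reference_type) if s in present]
        if not ref_libs:
            raise ContractError(f"lab {lab!r} has no {reference_type} replicates to center on")
        center = matrix.data[ref_libs].mean(axis=1)
        out[lab_libs] = matrix.data[lab_libs].sub(center, axis=0)
    return ExpressionMatrix(out, "log2fpkm")
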