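"""DEG ground-truth evaluation with the unreported-gene penalty.

A submission is scored against a truth set gene by gene. Truth DEGs that a
laboratory never reported are penalized as false negatives rather than
silently dropped, and the Matthews correlation coefficient of the resulting
confusion table is the headline accuracy score. A ranking AUC, a TaqMan-style
truth-labeling rule, a plain Welch-t internal caller, and the low-expression
filtering threshold sweep complete the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    ContractError,
    DegCallTable,
    ExpressionMatrix,
    GeneAnnotation,
    SampleSheet,
    TruthSet,
    to_log2,
)
from .normalization import normalize_fpkm, normalize_tc

__all__ = [
    "ConfusionTable",
    "FilterSpec",
    "label_truth_taqman_rule",
    "classify_calls",
    "mcc",
    "ranking_auc",
    "internal_deg_caller",
    "filter_sweep",
    "optimal_thresholds",
]


@dataclass
class ConfusionTable:
    tp: int
    tn: int
    fp: int
    fn: int
    n_unreported_truth_positives: int = 0  # subset of fn
    n_direction_errors: int = 0  # truth DEGs called with the opposite sign

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tpr(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def precision(self) -> float:
        called = self.tp + self.fp
        return self.tp / called if called else float("nan")


@dataclass(frozen=True)
class FilterSpec:
    """One low-expression filtering method: a statistic over replicates and
    the unit it is computed on."""

    statistic: str  # max | median | sum
    unit: str  # counts | cpm

    def __post_init__(self) -> None:
        if self.statistic not in ("max", "median", "sum"):
            raise ContractError(f"unknown statistic {self.statistic!r}")
        if self.unit not in ("counts", "cpm"):
            raise ContractError(f"unknown unit {self.unit!r}")

    def __str__(self) -> str:
        return f"{self.statistic}:{self.unit}"


def _two_group_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test on log2 values; returns (log2fc, p)."""
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, float)
    # zero variance in both groups: identical means -> p 1, else p 0
    degenerate = ~np.isfinite(p)
    p[degenerate] = np.where(np.isclose(log2fc[degenerate], 0.0), 1.0, 0.0)
    return log2fc, p


def label_truth_taqman_rule(
    group_values: pd.DataFrame,
    reference_values: pd.DataFrame,
    comparison: str,
    alpha: float = 0.05,
    fc_cut: float = 2.0,
) -> TruthSet:
    """Label DEGs from replicated log2 measurements, RT-qPCR style.

    A gene is a DEG when the Student t-test p < ``alpha`` AND its linear fold
    change is >= ``fc_cut`` or <= 1/``fc_cut``; direction follows the sign.
    Both inputs are genes x replicates on the log2 scale with matching index.
    """
    if group_values.shape[1] < 2 or reference_values.shape[1] < 2:
        raise ContractError("need >= 2 replicates per group")
    if not group_values.index.equals(reference_values.index):
        raise ContractError("group and reference tables must share the gene index")
    log2fc, p = _two_group_t(
        group_values.to_numpy(float), reference_values.to_numpy(float), equal_var=True
    )
    cut = math.log2(fc_cut)
    label = np.where(
        (p < alpha) & (np.abs(log2fc) >= cut),
        np.where(log2fc > 0, "up", "down"),
        "non_de",
    )
    df = pd.DataFrame(
        {"expected_log2fc": log2fc, "deg_label": label}, index=group_values.index
    )
    return TruthSet(comparison, df)


def classify_calls(
    truth: TruthSet,
    calls: DegCallTable,
    opposite_direction: str = "fn",
) -> ConfusionTable:
    """Confusion table of a call set against truth, penalizing absences.

    Every assessable truth gene (label up/down/non_de) lands in exactly one
    cell. Truth DEGs reported with the matching direction are TP; reported
    as not_de, reported with the opposite direction, or absent from the call
    table are FN (absences also counted in ``n_unreported_truth_positives``).
    Truth non-DE genes called up/down are FP; called not_de or absent are TN.
    Opposite-direction events are tallied separately; with
    ``opposite_direction="fp"`` they score FP instead of FN.
    """
    if truth.comparison != calls.comparison:
        raise ContractError(
            f"comparison mismatch: truth {truth.comparison!r} vs calls {calls.comparison!r}"
        )
    if opposite_direction not in ("fn", "fp"):
        raise ContractError("opposite_direction must be 'fn' or 'fp'")
    t = truth.data["deg_label"]
    assessable = t[t != "unassessed"]
    call = calls.data["call"].reindex(assessable.index).fillna("__absent__")

    truth_pos = assessable.isin(["up", "down"])
    match = (call == assessable) & truth_pos
    opposite = truth_pos & call.isin(["up", "down"]) & ~match
    absent = call == "__absent__"

    tp = int(match.sum())
    direction_errors = int(opposite.sum())
    unreported = int((truth_pos & absent).sum())
    if opposite_direction == "fn":
        fn = int((truth_pos & ~match).sum())
        fp_extra = 0
    else:
        fn = int((truth_pos & ~match & ~opposite).sum())
        fp_extra = direction_errors
    fp = int(((~truth_pos) & call.isin(["up", "down"])).sum()) + fp_extra
    tn = int(((~truth_pos) & (call.isin(["not_de"]) | absent)).sum())
    return ConfusionTable(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        n_unreported_truth_positives=unreported,
        n_direction_errors=direction_errors,
    )


def mcc(c: ConfusionTable) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def ranking_auc(
    truth: TruthSet,
    calls: DegCallTable,
    unreported: str = "worst",
) -> float:
    """AUC of the -log10(p) ranking for truth DEGs vs truth non-DE genes.

    Ties are mid-ranked (Mann-Whitney form). Truth genes absent from the
    call table are assigned the worst rank (``unreported="worst"``) or
    dropped (``"drop"``).
    """
    t = truth.data["deg_label"]
    assessable = t[t != "unassessed"]
    labels = assessable.isin(["up", "down"])
    p = calls.data["p"].reindex(assessable.index)
    with np.errstate(divide="ignore"):
        score = -np.log10(np.maximum(p.to_numpy(float), 1e-300))
    missing = p.isna().to_numpy()
    if unreported == "worst":
        finite_min = np.nanmin(score) if (~missing).any() else 0.0
        score[missing] = finite_min - 1.0
    elif unreported == "drop":
        score = score[~missing]
        labels = labels[~missing]
    else:
        raise ContractError("unreported must be 'worst' or 'drop'")
    y = labels.to_numpy(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 1 or n_neg < 1:
        raise ContractError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(score)  # mid-rank ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def internal_deg_caller(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    comparison: str,
    alpha: float = 0.05,
    fc_cut: float = 2.0,
    lab_id=None,
    correction: str = "none",
    recenter: bool = True,
) -> DegCallTable:
    """Plain Welch-t + fold-change caller on log2 expression (plumbing only;
    real submissions from edgeR/DESeq2/limma etc. enter as DegCallTable).

    With ``correction="bh"`` the significance cut is applied to
    Benjamini-Hochberg q-values instead of raw p-values, mimicking the
    FDR-controlled behavior of real differential-analysis tools. With
    ``recenter`` (default), each sample is shifted by its median log2
    deviation from the across-sample mean profile before testing — the
    log-space analogue of median-of-ratios size-factor normalization, which
    removes the composition offset that asymmetric differential expression
    imprints on depth-normalized values.
    """
    num_type, den_type = comparison.split("/")
    present = set(matrix.sample_ids)
    num = [s for s in sheet.libraries(lab_id=lab_id, sample_type=num_type) if s in present]
    den = [s for s in sheet.libraries(lab_id=lab_id, sample_type=den_type) if s in present]
    if len(num) < 2 or len(den) < 2:
        raise ContractError(f"need >= 2 replicates per side for {comparison}")
    a = matrix.data[num].to_numpy(float)
    b = matrix.data[den].to_numpy(float)
    if recenter:
        both = np.hstack([a, b])
        ref = both.mean(axis=1, keepdims=True)
        a = a - np.median(a - ref, axis=0, keepdims=True)
        b = b - np.median(b - ref, axis=0, keepdims=True)
    log2fc, p = _two_group_t(a, b, equal_var=False)
    if correction not in ("none", "bh"):
        raise ContractError("correction must be 'none' or 'bh'")
    q = _bh_adjust(p)
    sig = (q if correction == "bh" else p) < alpha
    cut = math.log2(fc_cut)
    call = np.where(
        sig & (np.abs(log2fc) >= cut),
        np.where(log2fc > 0, "up", "down"),
        "not_de",
    )
    df = pd.DataFrame({"log2fc": log2fc, "p": p, "q": q, "call": call}, index=matrix.gene_ids)
    return DegCallTable(comparison, df)


DEFAULT_THRESHOLDS = (0, 10, 20, 30, 40, 50, 60, 70)

DEFAULT_FILTER_SPECS = tuple(
    FilterSpec(statistic=s, unit=u) for s in ("max", "median", "sum") for u in ("counts", "cpm")
)


def filter_sweep(
    counts: ExpressionMatrix,
    sheet: SampleSheet,
    comparison: str,
    truth: TruthSet,
    specs=DEFAULT_FILTER_SPECS,
    thresholds=DEFAULT_THRESHOLDS,
    ann: GeneAnnotation | None = None,
    alpha: float = 0.05,
    fc_cut: float = 2.0,
    lab_id=None,
    correction: str = "bh",
) -> pd.DataFrame:
    """Low-expression filtering sweep: call DEGs after removing the lowest
    ``threshold`` percent of genes by each filter statistic, and score
    against truth (filtered truth DEGs count as false negatives).

    Returns one row per (statistic, unit, threshold) with n_kept, n_deg,
    tpr, precision and mcc. With an empty ``specs`` list a single unfiltered
    evaluation row is returned.
    """
    num_type, den_type = comparison.split("/")
    present = set(counts.sample_ids)
    libs = [
        s
        for s in sheet.libraries(lab_id=lab_id, sample_types=[num_type, den_type])
        if s in present
    ]
    sub_counts = counts.subset(samples=libs)
    if ann is not None:
        expr = to_log2(normalize_fpkm(sub_counts, ann))
    else:
        cpm_m = normalize_tc(sub_counts)
        expr = ExpressionMatrix(np.log2(cpm_m.data + 0.01), "log2fpkm")
    cpm = normalize_tc(sub_counts).data

    if not specs:
        calls = internal_deg_caller(
            expr, sheet, comparison, alpha, fc_cut, lab_id=lab_id, correction=correction
        )
        ct = classify_calls(truth, calls)
        return pd.DataFrame(
            [("none", "none", 0, counts.shape[0], calls.data["call"].isin(["up", "down"]).sum(),
              ct.tpr, ct.precision, mcc(ct))],
            columns=["statistic", "unit", "threshold_pct", "n_kept", "n_deg", "tpr",
                     "precision", "mcc"],
        )

    rows = []
    for spec in specs:
        base = sub_counts.data if spec.unit == "counts" else cpm
        stat = getattr(base, spec.statistic)(axis=1)
        for thr in thresholds:
            if not 0 <= thr <= 70:
                raise ContractError("thresholds are percentile points in [0, 70]")
            if thr == 0:
                keep = pd.Series(True, index=stat.index)
            else:
                cutoff = np.percentile(stat.to_numpy(float), thr)
                keep = stat > cutoff
            if not keep.any():
                warnings.warn(f"{spec}@{thr}% removes every gene; row skipped")
                continue
            filtered = expr.subset(genes=stat.index[keep])
            calls = internal_deg_caller(
                filtered, sheet, comparison, alpha, fc_cut, lab_id=lab_id,
                correction=correction,
            )
            ct = classify_calls(truth, calls)
            n_deg = int(calls.data["call"].isin(["up", "down"]).sum())
            rows.append(
                (spec.statistic, spec.unit, thr, int(keep.sum()), n_deg,
                 ct.tpr, ct.precision, mcc(ct))
            )
    return pd.DataFrame(
        rows,
        columns=["statistic", "unit", "threshold_pct", "n_kept", "n_deg", "tpr",
                 "precision", "mcc"],
    )


def optimal_thresholds(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per filtering method, the argmax-#DEG and argmax-TPR thresholds and
    the TPR observed at each."""
    rows = []
    for (statistic, unit), grp in sweep.groupby(["statistic", "unit"]):
        by_ndeg = grp.loc[grp["n_deg"].idxmax()]
        by_tpr = grp.loc[grp["tpr"].idxmax()]
        rows.append(
            (statistic, unit,
             by_ndeg["threshold_pct"], by_ndeg["tpr"],
             by_tpr["threshold_pct"], by_tpr["tpr"])
        )
    return pd.DataFrame(
        rows,
        columns=["statistic", "unit", "argmax_ndeg_threshold", "tpr_at_argmax_ndeg",
                 "argmax_tpr_threshold", "tpr_at_argmax_tpr"],
    )
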