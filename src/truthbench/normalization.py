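"""Count normalization: CPM/TC, FPKM, TPM, TMM, upper-quartile, median-of-ratios.

Within-sample methods (CPM, FPKM, TPM) return rescaled matrices directly.
Between-sample methods (TMM, UQ, median-of-ratios) return per-sample size
factors with the single orientation ``normalized value = count / factor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ContractError, ExpressionMatrix, GeneAnnotation

__all__ = [
    "SizeFactors",
    "normalize_tc",
    "normalize_fpkm",
    "normalize_tpm",
    "size_factors_tmm",
    "size_factors_uq",
    "size_factors_median_ratio",
    "apply_size_factors",
]


@dataclass
class SizeFactors:
    """Per-sample positive scaling factors; ``normalized = count / factor``."""

    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        v = self.factors.to_numpy(float)
        if not np.all(np.isfinite(v)) or (v <= 0).any():
            raise ContractError(f"{self.method} produced non-positive or non-finite factors")


def _require_counts(counts: ExpressionMatrix, op: str) -> None:
    if counts.scale != "counts":
        raise ContractError(f"{op} expects scale 'counts', got {counts.scale!r}")


def normalize_tc(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Total-count scaling (counts per million)."""
    _require_counts(counts, "normalize_tc")
    totals = counts.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ContractError(f"zero total counts in sample(s): {zero.index.tolist()}")
    return ExpressionMatrix(counts.data * 1e6 / totals, "cpm")


def normalize_fpkm(counts: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads."""
    _require_counts(counts, "normalize_fpkm")
    lengths_kb = ann.lengths(counts.gene_ids) / 1e3
    lib_millions = counts.data.sum(axis=0) / 1e6
    if (lib_millions == 0).any():
        raise ContractError("zero library size")
    fpkm = counts.data.div(lengths_kb.to_numpy(), axis=0).div(lib_millions, axis=1)
    return ExpressionMatrix(fpkm, "fpkm")


def normalize_tpm(counts: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Transcripts per million: length-rate first, then per-sample rescaling."""
    _require_counts(counts, "normalize_tpm")
    lengths_kb = ann.lengths(counts.gene_ids) / 1e3
    rate = counts.data.div(lengths_kb.to_numpy(), axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        raise ContractError("sample with no length-normalized signal")
    return ExpressionMatrix(rate * 1e6 / denom, "tpm")


def _rescale_geomean(factors: pd.Series) -> pd.Series:
    return factors / np.exp(np.log(factors).mean())


def size_factors_uq(counts: ExpressionMatrix) -> SizeFactors:
    """Upper-quartile factors: 75th percentile of counts after dropping all-zero genes."""
    _require_counts(counts, "size_factors_uq")
    kept = counts.data[(counts.data > 0).any(axis=1)]
    if kept.empty:
        raise ContractError("no nonzero genes")
    uq = kept.quantile(0.75, axis=0)
    zero = uq[uq == 0]
    if len(zero):
        raise ContractError(f"zero upper quartile in sample(s): {zero.index.tolist()}")
    return SizeFactors(_rescale_geomean(uq), "uq")


def size_factors_median_ratio(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios factors: per sample, the median over genes of
    count / geometric-mean-across-samples, using genes nonzero everywhere."""
    _require_counts(counts, "size_factors_median_ratio")
    everywhere = (counts.data > 0).all(axis=1)
    if not everywhere.any():
        raise ContractError("no gene with nonzero counts in every sample")
    sub = counts.data[everywhere]
    log_geomean = np.log(sub).mean(axis=1)
    log_ratios = np.log(sub).sub(log_geomean, axis=0)
    # median on the log scale (ties average geometrically), as DESeq does
    return SizeFactors(np.exp(log_ratios.median(axis=0)), "median_of_ratios")


def size_factors_tmm(
    counts: ExpressionMatrix,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> SizeFactors:
    """Trimmed mean of M-values size factors.

    The reference sample is the one whose upper quartile (computed on its
    nonzero counts) is closest to the mean upper quartile. For each test
    sample, M (log2 count-fraction ratio vs the reference) and A (mean log2
    abundance) are computed over genes nonzero in both; genes outside the
    central [trim, 1-trim] rank band of M (30%) or A (5%) are excluded, and
    the factor is 2 to the precision-weighted mean of the retained M values.
    Factors are rescaled so their geometric mean is 1.
    """
    _require_counts(counts, "size_factors_tmm")
    if counts.shape[1] < 2:
        raise ContractError("TMM needs at least two samples")
    data = counts.data
    lib = data.sum(axis=0).astype(float)

    def _uq_nonzero(col: pd.Series) -> float:
        nz = col[col > 0]
        return float(np.quantile(nz, 0.75)) if len(nz) else 0.0

    uqs = data.apply(_uq_nonzero, axis=0)
    ref = (uqs - uqs.mean()).abs().idxmin()

    raw = {}
    for sample in data.columns:
        if sample == ref:
            raw[sample] = lib[sample]
            continue
        obs, nref = data[sample].to_numpy(float), data[ref].to_numpy(float)
        both = (obs > 0) & (nref > 0)
        if not both.any():
            raise ContractError(f"no common nonzero genes between {sample!r} and {ref!r}")
        p_obs, p_ref = obs[both] / lib[sample], nref[both] / lib[ref]
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # delta-method precision weights for M
        w = 1.0 / (
            (lib[sample] - obs[both]) / (lib[sample] * obs[both])
            + (lib[ref] - nref[both]) / (lib[ref] * nref[both])
        )
        n = len(m)
        m_rank = np.argsort(np.argsort(m, kind="stable"), kind="stable") / n
        a_rank = np.argsort(np.argsort(a, kind="stable"), kind="stable") / n
        keep = (
            (m_rank >= logratio_trim)
            & (m_rank < 1 - logratio_trim)
            & (a_rank >= abundance_trim)
            & (a_rank < 1 - abundance_trim)
        )
        if not keep.any():  # tiny instances: fall back to untrimmed
            keep = np.ones(n, bool)
        tmm = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        raw[sample] = lib[sample] * 2.0**tmm
    return SizeFactors(_rescale_geomean(pd.Series(raw)[data.columns]), "tmm")


def apply_size_factors(counts: ExpressionMatrix, sf: SizeFactors) -> ExpressionMatrix:
    """Divide counts by per-sample factors (scale tag becomes 'normalized')."""
    _require_counts(counts, "apply_size_factors")
    missing = [s for s in counts.sample_ids if s not in sf.factors.index]
    if missing:
        raise ContractError(f"samples without size factors: {missing}")
    return ExpressionMatrix(counts.data / sf.factors[counts.sample_ids], "normalized")
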