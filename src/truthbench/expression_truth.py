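"""Accuracy of absolute and relative expression against truth sets.

Pearson r and RMSE against reference log2 values (TaqMan-style truth or
spike-in concentrations), recovery of per-gene expected log2 fold changes,
spike-in subgroup-ratio recovery stratified by concentration, and the
cross-contamination fraction of spike-in reads in samples that carry none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ContractError, ExpressionMatrix, SampleSheet, TruthSet

__all__ = [
    "AccuracyReport",
    "ErccTruth",
    "ERCC_SUBGROUP_RATIOS",
    "default_ercc_truth",
    "absolute_accuracy",
    "relative_accuracy",
    "ercc_ratio_recovery",
    "cross_contamination_fraction",
    "NO_SPIKEIN_TYPES",
]

#: Mix1:Mix2 concentration ratios for the four spike-in subgroups
ERCC_SUBGROUP_RATIOS = {"a": 4.0, "b": 0.5, "c": 2.0 / 3.0, "d": 1.0}

#: sample types that carry no spike-in mix
NO_SPIKEIN_TYPES = ("F7", "D5", "MAQC_A", "MAQC_B")


@dataclass
class ErccTruth:
    """Spike-in panel: per control, Mix 1 / Mix 2 concentrations and subgroup."""

    data: pd.DataFrame  # index ercc_id; columns conc_mix1, conc_mix2, subgroup

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ContractError("duplicate spike-in ids")
        if (self.data[["conc_mix1", "conc_mix2"]] <= 0).any().any():
            raise ContractError("spike-in concentrations must be positive")
        ratios = self.data["conc_mix1"] / self.data["conc_mix2"]
        for sub, expected in ERCC_SUBGROUP_RATIOS.items():
            got = ratios[self.data["subgroup"] == sub]
            if not np.allclose(got, expected, rtol=1e-9):
                raise ContractError(f"subgroup {sub!r} ratios deviate from {expected}")

    @property
    def ids(self) -> pd.Index:
        return self.data.index

    def expected_log2_ratio(self) -> pd.Series:
        """Expected log2(Mix1/Mix2) per spike-in."""
        return np.log2(self.data["conc_mix1"] / self.data["conc_mix2"])


def default_ercc_truth(
    n_per_subgroup: int = 23,
    dynamic_range_log2: float = 20.0,
    base_concentration: float = 15.0,
) -> ErccTruth:
    """The built-in 92-control spike-in template.

    Within each subgroup the Mix 1 concentrations follow a two-fold-style
    serial-dilution ladder spanning ``dynamic_range_log2`` doublings; Mix 2
    concentrations follow from the fixed subgroup ratios 4:1, 1:2, 2:3, 1:1.
    Concentrations are in arbitrary units (attomole-per-microliter-like).
    """
    rows = []
    steps = np.linspace(0.0, dynamic_range_log2, n_per_subgroup)
    for sub, ratio in ERCC_SUBGROUP_RATIOS.items():
        for i, step in enumerate(steps):
            conc1 = base_concentration * 2.0 ** (step - dynamic_range_log2 / 2.0)
            rows.append((f"SPIKEIN-{sub}{i + 1:02d}", conc1, conc1 / ratio, sub))
    df = pd.DataFrame(rows, columns=["ercc_id", "conc_mix1", "conc_mix2", "subgroup"])
    return ErccTruth(df.set_index("ercc_id"))


@dataclass
class AccuracyReport:
    label: str
    n_genes: int
    pearson_r: float
    rmse: float
    per_sample: pd.DataFrame | None = None  # per-sample r / rmse rows
    stratified: pd.DataFrame | None = None  # optional per-bin rows


def _pearson_rmse(obs: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    if obs.size < 2:
        raise ContractError("need at least 2 intersecting genes")
    if np.std(obs) == 0 or np.std(truth) == 0:
        r = 1.0 if np.allclose(obs, truth) else float("nan")
    else:
        r = float(stats.pearsonr(obs, truth).statistic)
    rmse = float(np.sqrt(np.mean((obs - truth) ** 2)))
    return r, rmse


def absolute_accuracy(
    matrix: ExpressionMatrix,
    truth_values: pd.Series,
    genes=None,
    label: str = "absolute",
) -> AccuracyReport:
    """Pearson r / RMSE of log2 expression against per-gene reference values.

    Metrics are computed per sample over the truth-and-data gene
    intersection; the headline numbers are the means over samples.
    """
    common = matrix.gene_ids.intersection(truth_values.index)
    if genes is not None:
        common = common.intersection(pd.Index(genes))
    if len(common) < 2:
        raise ContractError(
            f"only {len(common)} gene(s) shared between data and truth; need >= 2"
        )
    truth = truth_values.loc[common].to_numpy(float)
    rows = []
    for sample in matrix.sample_ids:
        obs = matrix.data.loc[common, sample].to_numpy(float)
        r, rmse = _pearson_rmse(obs, truth)
        rows.append((sample, r, rmse))
    per_sample = pd.DataFrame(rows, columns=["sample_id", "pearson_r", "rmse"]).set_index(
        "sample_id"
    )
    return AccuracyReport(
        label=label,
        n_genes=len(common),
        pearson_r=float(per_sample["pearson_r"].mean()),
        rmse=float(per_sample["rmse"].mean()),
        per_sample=per_sample,
    )


def relative_accuracy(
    rel_matrix: ExpressionMatrix,
    truth: TruthSet,
    sheet: SampleSheet | None = None,
    average_replicates: bool = True,
) -> AccuracyReport:
    """Observed relative expression (replicate-averaged) vs expected log2FC.

    If a sample sheet is given, the columns of the truth comparison's
    numerator sample type are selected automatically; otherwise all columns
    of ``rel_matrix`` are treated as numerator replicates.
    """
    if sheet is not None:
        cols = [
            s
            for s in sheet.libraries(sample_type=truth.numerator)
            if s in set(rel_matrix.sample_ids)
        ]
        if not cols:
            raise ContractError(f"no {truth.numerator} columns present for {truth.comparison}")
    else:
        cols = list(rel_matrix.sample_ids)
    common = rel_matrix.gene_ids.intersection(truth.data.index)
    if len(common) < 2:
        raise ContractError("need at least 2 intersecting genes")
    expected = truth.data.loc[common, "expected_log2fc"].to_numpy(float)
    sub = rel_matrix.data.loc[common, cols]
    if average_replicates:
        obs = sub.mean(axis=1).to_numpy(float)
        r, rmse = _pearson_rmse(obs, expected)
        per_sample = None
    else:
        rows = [
            (c, *_pearson_rmse(sub[c].to_numpy(float), expected)) for c in cols
        ]
        per_sample = pd.DataFrame(
            rows, columns=["sample_id", "pearson_r", "rmse"]
        ).set_index("sample_id")
        r = float(per_sample["pearson_r"].mean())
        rmse = float(per_sample["rmse"].mean())
    return AccuracyReport(
        label=truth.comparison, n_genes=len(common), pearson_r=r, rmse=rmse,
        per_sample=per_sample,
    )


def ercc_ratio_recovery(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    ercc: ErccTruth,
    n_bins: int = 4,
) -> AccuracyReport:
    """Observed log2(M8/D6) of each spike-in vs its expected subgroup ratio.

    The report is stratified into expected-concentration quantile bins
    (mean of the two mix concentrations), mirroring the observation that
    ratios recover better at higher abundance.
    """
    present = matrix.gene_ids.intersection(ercc.ids)
    if len(present) == 0:
        raise ContractError("no spike-in rows present in the matrix")
    m8 = [s for s in sheet.libraries(sample_type="M8") if s in set(matrix.sample_ids)]
    d6 = [s for s in sheet.libraries(sample_type="D6") if s in set(matrix.sample_ids)]
    if not m8 or not d6:
        raise ContractError("both M8 and D6 columns are required")
    obs = (
        matrix.data.loc[present, m8].mean(axis=1) - matrix.data.loc[present, d6].mean(axis=1)
    ).to_numpy(float)
    expected = ercc.expected_log2_ratio().loc[present].to_numpy(float)
    r, rmse = _pearson_rmse(obs, expected)

    conc = (
        (ercc.data.loc[present, "conc_mix1"] + ercc.data.loc[present, "conc_mix2"]) / 2.0
    )
    bins = pd.qcut(np.log2(conc), q=min(n_bins, len(present)), duplicates="drop")
    strat_rows = []
    for interval, idx in conc.groupby(bins, observed=True).groups.items():
        sel = present.get_indexer(idx)
        bin_rmse = float(np.sqrt(np.mean((obs[sel] - expected[sel]) ** 2)))
        strat_rows.append((str(interval), len(sel), bin_rmse))
    stratified = pd.DataFrame(strat_rows, columns=["conc_bin", "n_genes", "rmse"])
    return AccuracyReport(
        label="ercc_m8_vs_d6",
        n_genes=len(present),
        pearson_r=r,
        rmse=rmse,
        stratified=stratified,
    )


def cross_contamination_fraction(
    counts: ExpressionMatrix,
    sheet: SampleSheet,
    ercc_ids,
) -> pd.Series:
    """Spike-in read fraction per library, for sample types with no spike-in."""
    if counts.scale != "counts":
        raise ContractError(f"expects counts, got {counts.scale!r}")
    ercc_present = counts.gene_ids.intersection(pd.Index(ercc_ids))
    libs = [
        s for s in sheet.libraries(sample_types=NO_SPIKEIN_TYPES)
        if s in set(counts.sample_ids)
    ]
    totals = counts.data[libs].sum(axis=0)
    ercc_reads = counts.data.loc[ercc_present, libs].sum(axis=0)
    frac = (ercc_reads / totals).astype(float)
    frac.name = "ercc_fraction"
    return frac
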