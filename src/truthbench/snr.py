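"""PCA-based signal-to-noise ratio of expression data.

The SNR summarizes how well biological groups separate from replicate noise
in the plane of the first two principal components, each axis weighted by its
explained-variance fraction:

    Signal = mean squared distance between group centroids (unordered pairs)
    Noise  = mean squared distance of each replicate to its group centroid
    SNR    = 10 * log10(Signal / Noise)   [decibels]

A leave-one-out variant recomputes the SNR with each sample removed in turn;
a left-out sample whose removal raises the SNR by more than 6 dB is flagged
as a low-quality outlier (a "random failure").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContractError, ExpressionMatrix, SampleSheet

__all__ = [
    "SnrResult",
    "LeaveOneOutReport",
    "filter_genes_detected",
    "compute_snr",
    "leave_one_out_snr",
    "OUTLIER_DELTA_DB",
]

#: leave-one-out improvement (dB) above which the left-out sample is an outlier
OUTLIER_DELTA_DB = 6.0


@dataclass
class SnrResult:
    snr_db: float
    n_samples: int
    n_genes_used: int
    explained_variance: tuple[float, float]  # PC1, PC2 fractions
    coordinates: pd.DataFrame  # per-sample weighted (PC1, PC2) coords
    centroids: pd.DataFrame  # per-group centroid in the same plane
    signal: float
    noise: float


@dataclass
class LeaveOneOutReport:
    snr18: float
    table: pd.DataFrame  # index library_id: snr17, delta, outlier

    @property
    def outliers(self) -> list:
        return self.table.index[self.table["outlier"]].tolist()

    @property
    def max_delta(self) -> float:
        return float(self.table["delta"].max())


def filter_genes_detected(matrix: ExpressionMatrix, min_reads: int = 1) -> ExpressionMatrix:
    """Keep genes supported by >= ``min_reads`` in at least one sample."""
    if matrix.scale != "counts":
        raise ContractError(f"filter_genes_detected expects counts, got {matrix.scale!r}")
    keep = (matrix.data >= min_reads).any(axis=1)
    if not keep.any():
        raise ContractError("no gene passes the detection filter")
    return ExpressionMatrix(matrix.data[keep].copy(), "counts")


def _pca_plane(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance-scaled PCA over samples; returns (scores, evr fractions).

    ``x`` is samples x genes. Each gene (column) is centered and scaled to
    unit variance; zero-variance genes are dropped with a warning upstream.
    """
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0, ddof=1)
    xs = xc / sd
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    scores = u * s
    evr = s**2 / np.sum(s**2)
    return scores[:, :2], evr[:2]


def compute_snr(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    groups,
    noise_mode: str = "centroid",
) -> SnrResult:
    """PCA-based SNR over the samples of the listed sample-type groups.

    ``noise_mode`` selects the Noise term: squared replicate-to-centroid
    distances (default) or mean squared pairwise within-group distances.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ContractError("SNR needs at least two sample-type groups")
    if noise_mode not in ("centroid", "pairwise"):
        raise ContractError(f"unknown noise_mode {noise_mode!r}")
    libs = [s for s in sheet.libraries(sample_types=groups) if s in set(matrix.sample_ids)]
    type_of = sheet.sample_type_of()
    by_group = {g: [s for s in libs if type_of[s] == g] for g in groups}
    for g, members in by_group.items():
        if len(members) < 2:
            raise ContractError(f"group {g!r} has fewer than 2 replicates")

    x = matrix.data[libs].to_numpy(float).T  # samples x genes
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance gene(s) before PCA")
        x = x[:, sd > 0]
    if x.shape[1] < 2:
        raise ContractError("fewer than 2 informative genes for PCA")

    scores, evr = _pca_plane(x)
    coords = scores * evr  # weight each axis by its explained-variance fraction
    coords_df = pd.DataFrame(coords, index=libs, columns=["pc1", "pc2"])
    cent = {g: coords_df.loc[m].mean(axis=0).to_numpy() for g, m in by_group.items()}
    centroids = pd.DataFrame(cent, index=["pc1", "pc2"]).T

    signal = float(
        np.mean(
            [np.sum((cent[a] - cent[b]) ** 2) for a, b in itertools.combinations(groups, 2)]
        )
    )
    if noise_mode == "centroid":
        sq = [
            np.sum((coords_df.loc[s].to_numpy() - cent[g]) ** 2)
            for g, members in by_group.items()
            for s in members
        ]
        noise = float(np.mean(sq))
    else:
        sq = [
            np.sum((coords_df.loc[a].to_numpy() - coords_df.loc[b].to_numpy()) ** 2)
            for g, members in by_group.items()
            for a, b in itertools.combinations(members, 2)
        ]
        noise = float(np.mean(sq))

    # zero within numerical precision counts as zero (exact-replicate case)
    if noise <= 1e-12 * max(signal, 1.0):
        snr_db = float("inf")
    else:
        snr_db = 10.0 * np.log10(signal / noise)
    return SnrResult(
        snr_db=snr_db,
        n_samples=len(libs),
        n_genes_used=x.shape[1],
        explained_variance=(float(evr[0]), float(evr[1])),
        coordinates=coords_df,
        centroids=centroids,
        signal=signal,
        noise=noise,
    )


def leave_one_out_snr(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    groups,
    delta_db: float = OUTLIER_DELTA_DB,
    noise_mode: str = "centroid",
) -> LeaveOneOutReport:
    """Recompute the SNR with each sample left out; flag deltas > 6 dB."""
    groups = list(groups)
    full = compute_snr(matrix, sheet, groups, noise_mode=noise_mode)
    libs = full.coordinates.index.tolist()
    type_of = sheet.sample_type_of()
    counts = {g: sum(type_of[s] == g for s in libs) for g in groups}

    rows = []
    for left_out in libs:
        if counts[type_of[left_out]] - 1 < 2:
            warnings.warn(
                f"skipping {left_out!r}: its group would fall below 2 replicates"
            )
            continue
        sub = matrix.subset(samples=[s for s in libs if s != left_out])
        snr17 = compute_snr(sub, sheet, groups, noise_mode=noise_mode).snr_db
        delta = snr17 - full.snr_db
        rows.append((left_out, snr17, delta, delta > delta_db))
    table = pd.DataFrame(rows, columns=["library_id", "snr17", "delta", "outlier"]).set_index(
        "library_id"
    )
    return LeaveOneOutReport(snr18=full.snr_db, table=table)
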