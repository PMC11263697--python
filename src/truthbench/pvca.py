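"""Principal variance component analysis.

Variance in an expression matrix is attributed to named experimental or
biological factors in four steps: (i) PCA over samples (genes scaled to unit
variance) retaining the smallest set of leading components whose cumulative
explained variance reaches a threshold; (ii) for each retained component, a
variance-components model with one independent random effect per factor is
fitted by REML; (iii) per-term variance components are averaged across the
retained components, weighted by their eigenvalues; (iv) the weighted
averages, including the residual, are normalized into proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContractError, ExpressionMatrix, SampleSheet

__all__ = [
    "PvcaConfig",
    "VarianceDecomposition",
    "RemlResult",
    "AliasingWarning",
    "reml_variance_components",
    "run_pvca",
]


class AliasingWarning(UserWarning):
    """Two factors induce identical sample partitions; their variance
    components are not separately identifiable."""


@dataclass
class PvcaConfig:
    factors: list[str] = field(default_factory=list)
    variance_threshold: float = 0.6  # cumulative explained variance for PC retention
    include_pairwise_interactions: bool = False
    include_sample_group: bool = True  # biological term from sample_type
    continuous_bins: int = 4  # quartile binning for numeric factors
    reml_tol: float = 1e-9
    reml_max_iter: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold <= 1:
            raise ContractError("variance_threshold must lie in (0, 1]")


@dataclass
class RemlResult:
    components: dict  # term -> variance component
    residual: float
    converged: bool
    n_iter: int


@dataclass
class VarianceDecomposition:
    proportions: pd.Series  # per term + 'residual'; sums to 1
    weighted_components: pd.Series
    per_pc: pd.DataFrame  # term x PC variance components
    eigenvalues: np.ndarray
    n_pcs: int
    aliased_pairs: list

    def technical_proportion(self, biological_terms=("sample_group",)) -> float:
        tech = [
            t for t in self.proportions.index
            if t != "residual" and t not in biological_terms
        ]
        return float(self.proportions[tech].sum())

    def biological_proportion(self, biological_terms=("sample_group",)) -> float:
        present = [t for t in biological_terms if t in self.proportions.index]
        return float(self.proportions[present].sum())


def _indicator(levels: pd.Series) -> np.ndarray:
    codes, uniques = pd.factorize(levels, use_na_sentinel=False)
    z = np.zeros((len(codes), len(uniques)))
    z[np.arange(len(codes)), codes] = 1.0
    return z


def reml_variance_components(
    response,
    design: pd.DataFrame,
    tol: float = 1e-9,
    max_iter: int = 2000,
) -> RemlResult:
    """EM-REML for a variance-components model with independent random effects.

    ``response`` is one value per sample; ``design`` holds one categorical
    column per term. The model is y = mu + sum_k u_k + e with
    u_k ~ N(0, sigma_k^2 I); all components are non-negative by construction
    of the EM updates. Terms with a single level are dropped with a warning.
    """
    y = np.asarray(response, float)
    n = y.size
    if design.shape[0] != n:
        raise ContractError("design and response lengths differ")
    if design.shape[1] < 1:
        raise ContractError("need at least one term")
    if n < design.shape[1] + 1:
        raise ContractError("need more samples than terms")

    terms, z_mats = [], []
    for col in design.columns:
        levels = design[col].astype(str)
        if levels.nunique() < 2:
            warnings.warn(f"term {col!r} has a single level; dropped")
            continue
        terms.append(col)
        z_mats.append(_indicator(levels))
    var_y = float(np.var(y, ddof=1)) if n > 1 else 0.0
    if var_y == 0.0:
        return RemlResult({t: 0.0 for t in terms}, 0.0, converged=True, n_iter=0)
    if not terms:
        return RemlResult({}, var_y, converged=True, n_iter=0)

    k = len(terms)
    q = np.array([z.shape[1] for z in z_mats])
    sig = np.full(k, var_y / (k + 1))
    sig_e = var_y / (k + 1)
    ones = np.ones((n, 1))

    converged = False
    it = 0
    history: list[np.ndarray] = []
    for it in range(1, max_iter + 1):
        v = sig_e * np.eye(n)
        for s, z in zip(sig, z_mats):
            v += s * (z @ z.T)
        vinv = np.linalg.inv(v)
        vinv1 = vinv @ ones
        p = vinv - (vinv1 @ vinv1.T) / float((ones.T @ vinv1)[0, 0])
        py = p @ y

        new_sig = np.empty(k)
        for j, z in enumerate(z_mats):
            ztpy = z.T @ py
            ztpz = z.T @ p @ z
            # E[u'u | y] with u_hat = sig_j * Z' P y
            new_sig[j] = (
                sig[j] ** 2 * float(ztpy @ ztpy)
                + sig[j] * q[j]
                - sig[j] ** 2 * float(np.trace(ztpz))
            ) / q[j]
        new_sig_e = (
            sig_e**2 * float(py @ py) + sig_e * n - sig_e**2 * float(np.trace(p))
        ) / n
        new_sig = np.maximum(new_sig, 0.0)
        # EM decays to the zero boundary sublinearly; make it absorbing
        new_sig[new_sig < 1e-8 * var_y] = 0.0
        new_sig_e = max(new_sig_e, 1e-12 * var_y)

        delta = max(
            np.max(np.abs(new_sig - sig)) if k else 0.0, abs(new_sig_e - sig_e)
        ) / max(var_y, 1e-300)
        sig, sig_e = new_sig, new_sig_e
        if delta < tol:
            converged = True
            break

        # safeguarded Aitken extrapolation collapses EM's geometric tail
        history.append(np.append(sig, sig_e))
        if len(history) == 3:
            s0, s1, s2 = history
            d1, d2 = s1 - s0, s2 - s1
            denom = d2 - d1
            safe = np.abs(denom) > 1e-300
            accel = s2.copy()
            accel[safe] = s2[safe] - d2[safe] ** 2 / denom[safe]
            if np.all(accel[:-1] >= 0) and accel[-1] > 0:
                sig, sig_e = accel[:-1], float(accel[-1])
                sig[sig < 1e-10 * var_y] = 0.0
            history = []
    if not converged:
        warnings.warn(f"EM-REML did not converge after {max_iter} iterations")
    return RemlResult(dict(zip(terms, sig.tolist())), float(sig_e), converged, it)


def _binned(col: pd.Series, bins: int) -> pd.Series:
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > bins:
        return pd.qcut(col, q=bins, duplicates="drop").astype(str)
    return col.astype(str)


def run_pvca(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    config: PvcaConfig,
) -> VarianceDecomposition:
    """Eigenvalue-weighted variance-source decomposition of an expression matrix."""
    libs = [s for s in sheet.data["library_id"] if s in set(matrix.sample_ids)]
    if len(libs) < 3:
        raise ContractError("PVCA needs at least 3 samples")
    meta = sheet.data.set_index("library_id").loc[libs]

    design = pd.DataFrame(index=meta.index)
    for f in config.factors:
        if f not in meta.columns:
            raise ContractError(f"factor {f!r} not present in the sample sheet")
        design[f] = _binned(meta[f], config.continuous_bins)
    if config.include_sample_group:
        design["sample_group"] = meta["sample_type"].astype(str)
    if config.include_pairwise_interactions:
        base = [c for c in design.columns]
        for i in range(len(base)):
            for j in range(i + 1, len(base)):
                combo = design[base[i]] + ":" + design[base[j]]
                # require replicated combination levels for identifiability
                if combo.value_counts().min() >= 2 and combo.nunique() > 1:
                    design[f"{base[i]}x{base[j]}"] = combo

    # aliasing: identical induced partitions are not separately identifiable
    aliased = []
    cols = list(design.columns)
    part = {c: pd.factorize(design[c])[0].tolist() for c in cols}
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if part[cols[i]] == part[cols[j]]:
                aliased.append((cols[i], cols[j]))
    if aliased:
        warnings.warn(
            f"aliased factors (identical sample partitions): {aliased}; "
            "their variance split is arbitrary",
            AliasingWarning,
        )

    x = matrix.data[libs].to_numpy(float).T  # samples x genes
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0, ddof=1)
    xs = xc[:, sd > 0] / sd[sd > 0]
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    eig = s**2 / (len(libs) - 1)
    evr = eig / eig.sum()
    n_pcs = int(np.searchsorted(np.cumsum(evr), config.variance_threshold) + 1)
    n_pcs = min(max(n_pcs, 1), len(libs) - 1)
    if n_pcs >= len(libs):
        raise ContractError("more retained components than samples")
    scores = u * s

    per_pc = {}
    for pc in range(n_pcs):
        res = reml_variance_components(
            scores[:, pc], design, tol=config.reml_tol, max_iter=config.reml_max_iter
        )
        comp = dict(res.components)
        comp["residual"] = res.residual
        per_pc[f"PC{pc + 1}"] = comp
    per_pc_df = pd.DataFrame(per_pc).fillna(0.0)

    w = eig[:n_pcs]
    weighted = per_pc_df.mul(w, axis=1).sum(axis=1) / w.sum()
    total = weighted.sum()
    proportions = weighted / total if total > 0 else weighted
    order = [c for c in design.columns if c in proportions.index] + ["residual"]
    return VarianceDecomposition(
        proportions=proportions[order],
        weighted_components=weighted[order],
        per_pc=per_pc_df.reindex(order),
        eigenvalues=eig[:n_pcs],
        n_pcs=n_pcs,
        aliased_pairs=aliased,
    )
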