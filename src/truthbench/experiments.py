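"""Seeded benchmark experiments exercising the assessment end to end.

Each function generates its own inputs (via the synthetic panel or a direct
construction), runs the package's methods, and returns summary numbers.
These drive the acceptance workflow and are sized to run on a single CPU in
a few minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    MAQC_TYPES,
    MIXTURE_TYPES,
    QUARTET_TYPES,
    SampleSheet,
    relative_expression,
    to_log2,
)
from .mixing import MixtureModel, estimate_z, fit_mixture_curve
from .deg import filter_sweep, optimal_thresholds
from .pvca import PvcaConfig, reml_variance_components, run_pvca
from .simulate import SimulationConfig, simulate_panel
from .snr import compute_snr, leave_one_out_snr

QUARTET_AND_MIX = list(QUARTET_TYPES + MIXTURE_TYPES)

Z_GRID = (0.90, 0.95, 1.00)


def _seed(base: int, offset: int) -> int:
    return (int(base) * 1_000_003 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# titration z recovery


def z_recovery_noise_free(seed: int, n_genes: int = 200) -> float:
    """Max |z_hat - z*| over the z* grid, both mixtures and both coefficient
    modes, from noise-free abundances (closed-form / root-finding path)."""
    rng = np.random.default_rng(_seed(seed, 1))
    worst = 0.0
    for zstar in Z_GRID:
        for which in MIXTURE_TYPES:
            for mode in ("as_printed", "mass_balance"):
                base = rng.normal(1, 2, n_genes)
                fc = rng.normal(0, 1.5, n_genes)
                d6 = 2.0**base
                m8 = d6 * 2.0**fc
                w_m8, w_d6 = MixtureModel(zstar, mode).weights(which)
                mix = w_m8 * m8 + w_d6 * d6
                est = estimate_z(m8, d6, mix, which, mode=mode)
                worst = max(worst, abs(est.z - zstar))
    return worst


def z_recovery_noisy(
    seed: int,
    n_runs: int = 100,
    n_genes: int = 2000,
    noise_sd: float = 0.1,
    tolerance: float = 0.02,
) -> dict:
    """Robust-curve-fit recovery of z* under multiplicative log-normal noise
    (sd ``noise_sd`` natural log) on each measured abundance.

    Returns the fraction of runs with |z_hat - z*| < ``tolerance``.
    """
    errors = []
    for run in range(n_runs):
        rng = np.random.default_rng(_seed(seed, 100 + run))
        zstar = Z_GRID[run % len(Z_GRID)]
        which = MIXTURE_TYPES[run % 2]
        base = rng.normal(1, 2, n_genes)
        fc = rng.normal(0, 1.5, n_genes)
        d6 = 2.0**base
        m8 = d6 * 2.0**fc
        w_m8, w_d6 = MixtureModel(zstar, "as_printed").weights(which)
        mix = w_m8 * m8 + w_d6 * d6

        def noisy():
            return np.exp(rng.normal(0.0, noise_sd, n_genes))

        x = np.log2(m8 * noisy() / (d6 * noisy()))
        y = np.log2(mix * noisy() / (d6 * noisy()))
        fit = fit_mixture_curve(x, y, which, mode="as_printed", z_reference=zstar)
        errors.append(abs(fit.z - zstar))
    errors = np.asarray(errors)
    return {
        "pass_fraction": float((errors < tolerance).mean()),
        "median_error": float(np.median(errors)),
        "max_error": float(errors.max()),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# SNR experiments


def make_replicated_groups(
    rng,
    n_genes: int = 300,
    groups=QUARTET_AND_MIX,
    replicates: int = 3,
    group_sd: float = 0.5,
    noise_sd: float = 0.2,
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Log2 matrix with per-gene group means and replicate noise."""
    gm = rng.normal(0.0, group_sd, (n_genes, len(groups)))
    cols, rows = {}, []
    for gi, stype in enumerate(groups):
        for r in range(1, replicates + 1):
            lib = f"lab01_{stype}_r{r}"
            cols[lib] = gm[:, gi] + rng.normal(0.0, noise_sd, n_genes)
            rows.append(
                {"library_id": lib, "lab_id": "lab01", "sample_type": stype,
                 "replicate": r}
            )
    matrix = ExpressionMatrix(
        pd.DataFrame(cols, index=[f"g{i:05d}" for i in range(n_genes)]), "log2fpkm"
    )
    return matrix, SampleSheet(pd.DataFrame(rows))


def planted_outlier_detection(
    seed: int,
    n_runs: int = 100,
    n_genes: int = 300,
    displacement_sd: float = 2.0,
) -> dict:
    """Fraction of runs in which the displaced replicate — and only it — is
    flagged by the leave-one-out 6 dB rule."""
    hits = 0
    for run in range(n_runs):
        rng = np.random.default_rng(_seed(seed, 500 + run))
        matrix, sheet = make_replicated_groups(rng, n_genes=n_genes)
        victim = matrix.sample_ids[int(rng.integers(matrix.shape[1]))]
        matrix.data[victim] += rng.normal(0.0, displacement_sd, n_genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = leave_one_out_snr(matrix, sheet, QUARTET_AND_MIX)
        hits += report.outliers == [victim]
    return {"detection_fraction": hits / n_runs, "n_runs": n_runs}


def snr_sample_contrast(
    seed: int, n_genes: int = 1200, n_labs: int = 3
) -> dict:
    """Per-lab SNR of the subtle-difference (Quartet + mixtures) panel vs the
    large-difference (MAQC) pair on the default simulation."""
    cfg = SimulationConfig(n_genes=n_genes, n_labs=n_labs, seed=_seed(seed, 7))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts, fpkm, sheet, truth = simulate_panel(cfg)
        log2m = to_log2(fpkm)
        human = [g for g in log2m.gene_ids if g not in set(truth.ercc.ids)]
        log2m = log2m.subset(genes=human)
        quartet, maqc = [], []
        for lab in sheet.labs:
            sub = log2m.subset(samples=sheet.libraries(lab_id=lab))
            quartet.append(compute_snr(sub, sheet, QUARTET_AND_MIX).snr_db)
            maqc.append(compute_snr(sub, sheet, list(MAQC_TYPES)).snr_db)
    return {
        "snr_quartet_mean": float(np.mean(quartet)),
        "snr_maqc_mean": float(np.mean(maqc)),
        "quartet_below_maqc": bool(np.mean(quartet) < np.mean(maqc)),
    }


# ---------------------------------------------------------------------------
# PVCA experiments


def pvca_crossed_ordering(
    seed: int,
    n_runs: int = 100,
    levels: int = 8,
    replicates: int = 2,
    var_a: float = 4.0,
    var_b: float = 0.5,
    var_e: float = 1.0,
) -> dict:
    """Fraction of crossed two-factor simulations in which REML recovers the
    planted variance ordering (var_a > var_b)."""
    hits = 0
    for run in range(n_runs):
        rng = np.random.default_rng(_seed(seed, 900 + run))
        ea = rng.normal(0, np.sqrt(var_a), levels)
        eb = rng.normal(0, np.sqrt(var_b), levels)
        rows = []
        for i in range(levels):
            for j in range(levels):
                for _ in range(replicates):
                    rows.append(
                        (f"a{i}", f"b{j}",
                         ea[i] + eb[j] + rng.normal(0, np.sqrt(var_e)))
                    )
        df = pd.DataFrame(rows, columns=["A", "B", "y"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = reml_variance_components(df["y"], df[["A", "B"]])
        hits += res.components["A"] > res.components["B"]
    return {"ordering_fraction": hits / n_runs, "n_runs": n_runs}


def pvca_quartet_maqc_contrast(
    seed: int, n_genes: int = 1500, n_labs: int = 8
) -> dict:
    """Technical vs biological variance proportions on the default panel:
    subtle-difference samples should be technically dominated, the
    large-difference pair biologically dominated."""
    cfg = SimulationConfig(n_genes=n_genes, n_labs=n_labs, seed=_seed(seed, 11))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts, fpkm, sheet, truth = simulate_panel(cfg, with_ercc=False)
        log2m = to_log2(fpkm)
        pcfg = PvcaConfig(factors=sheet.factor_names)
        vq = run_pvca(
            log2m.subset(samples=sheet.libraries(sample_types=QUARTET_TYPES)),
            sheet, pcfg,
        )
        vm = run_pvca(
            log2m.subset(samples=sheet.libraries(sample_types=MAQC_TYPES)),
            sheet, pcfg,
        )
    return {
        "quartet_technical_pct": 100 * vq.technical_proportion(),
        "quartet_biological_pct": 100 * vq.biological_proportion(),
        "maqc_technical_pct": 100 * vm.technical_proportion(),
        "maqc_biological_pct": 100 * vm.biological_proportion(),
    }


def pvca_anova_agreement(seed: int, n_levels: int = 8, replicates: int = 4) -> float:
    """Max |REML - closed-form ANOVA| on a balanced one-way design."""
    rng = np.random.default_rng(_seed(seed, 13))
    eff = rng.normal(0, 2.0, n_levels)
    y = np.repeat(eff, replicates) + rng.normal(0, 1.0, n_levels * replicates)
    design = pd.DataFrame(
        {"f": np.repeat([f"l{i}" for i in range(n_levels)], replicates)}
    )
    res = reml_variance_components(y, design)
    grp = y.reshape(n_levels, replicates)
    msw = float(grp.var(axis=1, ddof=1).mean())
    msb = replicates * float(grp.mean(axis=1).var(ddof=1))
    sb = max((msb - msw) / replicates, 0.0)
    return max(abs(res.components["f"] - sb), abs(res.residual - msw))


# ---------------------------------------------------------------------------
# filtering sweep


def filter_threshold_consistency(
    seed: int, n_genes: int = 3000, comparison: str = "MAQC_A/MAQC_B"
) -> dict:
    """Gap between the sensitivity at the practical (max #DEG) and at the
    oracle (max TPR) filtering thresholds, over all six filter methods."""
    cfg = SimulationConfig(n_genes=n_genes, n_labs=1, seed=_seed(seed, 17))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts, fpkm, sheet, truth = simulate_panel(cfg, with_ercc=False)
        sweep = filter_sweep(
            counts, sheet, comparison, truth.truth_sets[comparison],
            ann=truth.annotation,
        )
    opt = optimal_thresholds(sweep)
    gaps = (opt["tpr_at_argmax_tpr"] - opt["tpr_at_argmax_ndeg"]).abs()
    return {
        "max_tpr_gap": float(gaps.max()),
        "tpr_at_argmax_ndeg_mean": float(opt["tpr_at_argmax_ndeg"].mean()),
        "tpr_at_argmax_tpr_mean": float(opt["tpr_at_argmax_tpr"].mean()),
    }
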