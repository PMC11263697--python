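"""Synthetic multi-laboratory reference-panel generator.

Emulates the eight-sample proficiency panel: four family-quartet-like
samples (M8, F7, D5, D6) with subtle expression differences, two reference
samples with large differences (MAQC_A, MAQC_B), two titration mixtures of
M8 and D6 at 3:1 and 1:3 with an mRNA-fraction shift z, and a 92-control
spike-in panel in two mixes. Per-laboratory technical effects (protocol
factors, batch), replicate noise and negative-binomial counting noise are
planted with known magnitudes, and every planted quantity is recorded in a
truth object so downstream metrics can be scored against ground truth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_truth import ERCC_SUBGROUP_RATIOS, ErccTruth, default_ercc_truth
from .io import (
    ContractError,
    ExpressionMatrix,
    GeneAnnotation,
    SampleSheet,
    SAMPLE_TYPES,
    TruthSet,
)
from .mixing import MixtureModel

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "build_sample_panel",
    "simulate_expression",
    "spike_ercc",
    "simulate_panel",
]

DEFAULT_FACTOR_LEVELS = {
    "enrichment": ("polya", "ribo_depletion"),
    "strandedness": ("stranded", "unstranded"),
    "kit": ("kit1", "kit2", "kit3"),
}

DEFAULT_FACTOR_EFFECT_SDS = {"enrichment": 1.0, "strandedness": 0.6, "kit": 0.4}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel (all effects on log2 scale)."""

    n_genes: int = 5000
    n_labs: int = 45
    replicates: int = 3
    quartet_deg_fraction: float = 0.05
    quartet_effect_sd: float = 0.8
    #: the twin sample's effect scale relative to quartet_effect_sd
    twin_effect_scale: float = 0.4
    maqc_deg_fraction: float = 0.5
    maqc_effect_sd: float = 3.0
    z_t1: float = 0.974
    z_t2: float = 0.949
    mixture_mode: str = "as_printed"
    factor_effect_sds: dict = field(default_factory=lambda: dict(DEFAULT_FACTOR_EFFECT_SDS))
    factor_levels: dict = field(default_factory=lambda: dict(DEFAULT_FACTOR_LEVELS))
    fully_crossed_factors: bool = False
    batch_effect_sd: float = 0.3
    replicate_noise_sd: float = 0.2
    library_size_range: tuple = (2_000_000, 8_000_000)
    dispersion: float = 0.05  # NB: var = mu + dispersion * mu^2; 0 => deterministic
    baseline_mean_log2: float = 1.0
    baseline_sd_log2: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "quartet_effect_sd", "maqc_effect_sd", "batch_effect_sd",
            "replicate_noise_sd", "dispersion",
        ):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be >= 0")
        for name in ("quartet_deg_fraction", "maqc_deg_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ContractError(f"{name} must lie in [0, 1]")
        if self.z_t1 <= 0 or self.z_t2 <= 0:
            raise ContractError("z must be positive")
        if any(sd < 0 for sd in self.factor_effect_sds.values()):
            raise ContractError("factor effect sds must be >= 0")
        if set(self.factor_effect_sds) - set(self.factor_levels):
            raise ContractError("every factor with an effect sd needs a level set")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ContractError("invalid library size range")


@dataclass
class SimulationTruth:
    """Everything planted by the generator, recorded (never re-estimated)."""

    truth_sets: dict  # comparison -> TruthSet
    z_t1: float
    z_t2: float
    ercc: ErccTruth
    factor_effect_sds: dict
    lab_factor_levels: pd.DataFrame  # lab_id x factor
    baseline_log2: pd.Series  # per-gene baseline (D6) log2 relative abundance
    type_effects_log2: pd.DataFrame  # gene x sample_type planted shifts
    gene_lengths: pd.Series
    annotation: GeneAnnotation


def build_sample_panel(config: SimulationConfig) -> SampleSheet:
    """Library rows for 8 sample types x replicates x labs, with per-lab
    factor levels (each lab runs one protocol level per factor)."""
    rng = np.random.default_rng(config.seed)
    labs = [f"lab{i + 1:02d}" for i in range(config.n_labs)]

    factor_names = list(config.factor_levels)
    if config.fully_crossed_factors and factor_names:
        combos = list(itertools.product(*(config.factor_levels[f] for f in factor_names)))
        assignment = [combos[i % len(combos)] for i in range(config.n_labs)]
    else:
        assignment = [
            tuple(rng.choice(config.factor_levels[f]) for f in factor_names)
            for _ in range(config.n_labs)
        ]

    rows = []
    for lab, combo in zip(labs, assignment):
        for stype in SAMPLE_TYPES:
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "library_id": f"{lab}_{stype}_r{rep}",
                        "lab_id": lab,
                        "sample_type": stype,
                        "replicate": rep,
                        **dict(zip(factor_names, combo)),
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def _planted_effects(
    rng: np.random.Generator, n_genes: int, fraction: float, sd: float
) -> np.ndarray:
    """Sparse per-gene log2 shifts: a random subset of genes gets an effect
    drawn from +/- |N(0, sd)|, guaranteed nonzero for selected genes."""
    effects = np.zeros(n_genes)
    n_deg = int(round(fraction * n_genes))
    if n_deg == 0 or sd == 0:
        return effects
    idx = rng.choice(n_genes, size=n_deg, replace=False)
    magnitude = np.abs(rng.normal(0.0, sd, size=n_deg)) + 0.1
    sign = rng.choice([-1.0, 1.0], size=n_deg)
    effects[idx] = sign * magnitude
    return effects


def _truth_from_effects(comparison: str, genes, effects: np.ndarray) -> TruthSet:
    label = np.where(effects > 0, "up", np.where(effects < 0, "down", "non_de"))
    return TruthSet(
        comparison,
        pd.DataFrame({"expected_log2fc": effects, "deg_label": label}, index=genes),
    )


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimulationTruth]:
    """Generate (counts, fpkm, truth) for the full multi-laboratory panel.

    Per-gene baseline log2 abundance is Gaussian (long-tailed on the linear
    scale); sample-type effects are sparse planted shifts; mixture abundances
    follow the titration weights at the true z; per-lab factor, batch and
    replicate effects are added on the log scale; counts are drawn from a
    negative binomial around expected fragment counts, and FPKM is derived
    from the realized counts, gene lengths and library sizes.
    """
    rng = np.random.default_rng(config.seed)
    sheet = build_sample_panel(config)
    g = config.n_genes
    genes = pd.Index([f"GENE{i + 1:05d}" for i in range(g)], name="gene_id")

    lengths = np.clip(
        np.round(rng.lognormal(np.log(1500.0), 0.7, size=g)), 200, 50_000
    ).astype(int)
    ann = GeneAnnotation(
        pd.DataFrame(
            {"length_bp": lengths, "gene_type": "protein_coding"}, index=genes
        )
    )

    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=g)

    eff = {
        "D6": np.zeros(g),
        "M8": _planted_effects(rng, g, config.quartet_deg_fraction, config.quartet_effect_sd),
        "F7": _planted_effects(rng, g, config.quartet_deg_fraction, config.quartet_effect_sd),
        "D5": _planted_effects(
            rng, g, config.quartet_deg_fraction,
            config.quartet_effect_sd * config.twin_effect_scale,
        ),
    }
    maqc_b_shift = rng.normal(0.0, 0.5, size=g)  # independent tissue baseline
    eff["MAQC_B"] = maqc_b_shift
    eff["MAQC_A"] = maqc_b_shift + _planted_effects(
        rng, g, config.maqc_deg_fraction, config.maqc_effect_sd
    )

    # titration mixtures on the linear scale at the true z
    lin_m8 = 2.0 ** (baseline + eff["M8"])
    lin_d6 = 2.0**baseline
    for which, z in (("T1", config.z_t1), ("T2", config.z_t2)):
        model = MixtureModel(z, config.mixture_mode)
        w_m8, w_d6 = model.weights(which)
        eff[which] = np.log2(w_m8 * lin_m8 + w_d6 * lin_d6) - baseline

    type_effects = pd.DataFrame(eff, index=genes)

    truth_sets = {
        "M8/D6": _truth_from_effects("M8/D6", genes, eff["M8"]),
        "F7/D6": _truth_from_effects("F7/D6", genes, eff["F7"]),
        "D5/D6": _truth_from_effects("D5/D6", genes, eff["D5"]),
        "MAQC_A/MAQC_B": _truth_from_effects(
            "MAQC_A/MAQC_B", genes, eff["MAQC_A"] - eff["MAQC_B"]
        ),
    }

    # per-lab technical structure
    factor_names = list(config.factor_levels)
    level_effects = {
        f: {
            lvl: rng.normal(0.0, config.factor_effect_sds.get(f, 0.0), size=g)
            for lvl in config.factor_levels[f]
        }
        for f in factor_names
    }
    labs = sheet.labs
    lab_levels = (
        sheet.data[["lab_id"] + factor_names].drop_duplicates().set_index("lab_id")
    )
    lab_shift = {}
    for lab in labs:
        shift = rng.normal(0.0, config.batch_effect_sd, size=g)
        for f in factor_names:
            shift = shift + level_effects[f][lab_levels.loc[lab, f]]
        lab_shift[lab] = shift

    lo, hi = config.library_size_range
    lengths_kb = lengths / 1e3
    counts_cols, meta = {}, sheet.data
    for row in meta.itertuples(index=False):
        x = (
            baseline
            + type_effects[row.sample_type].to_numpy()
            + lab_shift[row.lab_id]
        )
        if config.replicate_noise_sd > 0:
            x = x + rng.normal(0.0, config.replicate_noise_sd, size=g)
        rel = 2.0**x * lengths_kb  # expected fragment share per gene
        lib_size = lo if lo == hi else rng.integers(lo, hi + 1)
        mu = rel / rel.sum() * lib_size
        if config.dispersion == 0:
            counts_cols[row.library_id] = np.round(mu).astype(np.int64)
        else:
            r = 1.0 / config.dispersion
            counts_cols[row.library_id] = rng.negative_binomial(
                r, r / (r + mu)
            ).astype(np.int64)
    counts = ExpressionMatrix(pd.DataFrame(counts_cols, index=genes), "counts")

    lib = counts.data.sum(axis=0) / 1e6
    fpkm = ExpressionMatrix(
        counts.data.div(lengths_kb, axis=0).div(lib, axis=1), "fpkm"
    )

    truth = SimulationTruth(
        truth_sets=truth_sets,
        z_t1=config.z_t1,
        z_t2=config.z_t2,
        ercc=default_ercc_truth(),
        factor_effect_sds=dict(config.factor_effect_sds),
        lab_factor_levels=lab_levels,
        baseline_log2=pd.Series(baseline, index=genes, name="baseline_log2"),
        type_effects_log2=type_effects,
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
        annotation=ann,
    )
    return counts, fpkm, truth


def spike_ercc(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    ercc: ErccTruth,
    z_t1: float = 0.974,
    z_t2: float = 0.949,
    mixture_mode: str = "as_printed",
    concentration_to_value: float = 1.0,
    noise_sd_log2: float = 0.0,
    contamination_rate: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Append the spike-in rows to an expression matrix.

    Mix 1 concentrations drive M8 columns, Mix 2 drives D6, and the
    titration mixtures receive the z-corrected blend of the two mixes;
    samples without spike-ins get 0 (plus an optional small contamination
    fraction of the mean spiked value). Works for 'fpkm' and 'counts'
    matrices (counts are rounded to integers).
    """
    collision = matrix.gene_ids.intersection(ercc.ids)
    if len(collision):
        raise ContractError(f"spike-in ids already present: {collision.tolist()[:5]}")
    rng = np.random.default_rng(seed)
    conc1 = ercc.data["conc_mix1"].to_numpy() * concentration_to_value
    conc2 = ercc.data["conc_mix2"].to_numpy() * concentration_to_value
    blend = {}
    for which, z in (("T1", z_t1), ("T2", z_t2)):
        w_m8, w_d6 = MixtureModel(z, mixture_mode).weights(which)
        blend[which] = w_m8 * conc1 + w_d6 * conc2
    per_type = {
        "M8": conc1,
        "D6": conc2,
        "T1": blend["T1"],
        "T2": blend["T2"],
    }
    background = contamination_rate * np.mean((conc1 + conc2) / 2.0)

    type_of = sheet.sample_type_of()
    new_rows = {}
    for sample in matrix.sample_ids:
        base = per_type.get(type_of.get(sample), None)
        vals = background * np.ones_like(conc1) if base is None else base.copy()
        if noise_sd_log2 > 0:
            vals = vals * 2.0 ** rng.normal(0.0, noise_sd_log2, size=vals.size)
        new_rows[sample] = np.round(vals).astype(np.int64) if matrix.scale == "counts" else vals
    appended = pd.DataFrame(new_rows, index=ercc.ids)[list(matrix.sample_ids)]
    return ExpressionMatrix(pd.concat([matrix.data, appended]), matrix.scale)


def simulate_panel(config: SimulationConfig, with_ercc: bool = True):
    """Convenience wrapper: full simulation, spike-ins included on both the
    counts and FPKM matrices. Returns (counts, fpkm, sheet, truth)."""
    counts, fpkm, truth = simulate_expression(config)
    sheet = build_sample_panel(config)
    if with_ercc:
        median_count = float(np.median(counts.data.to_numpy())) or 1.0
        kwargs = dict(
            z_t1=config.z_t1,
            z_t2=config.z_t2,
            mixture_mode=config.mixture_mode,
            noise_sd_log2=config.replicate_noise_sd,
            seed=config.seed + 1,
        )
        counts = spike_ercc(
            counts, sheet, truth.ercc,
            concentration_to_value=median_count / 15.0, **kwargs,
        )
        fpkm = spike_ercc(
            fpkm, sheet, truth.ercc, concentration_to_value=1.0, **kwargs,
        )
    return counts, fpkm, sheet, truth
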