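"""End-to-end assessment pipeline over the synthetic panel.

Runs simulate -> normalize -> SNR -> truth evaluations -> PVCA -> QC flags
and aggregates everything into one JSON-serializable report plus a run
manifest. Stage failures abort with the stage name.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deg import classify_calls, internal_deg_caller, mcc, ranking_auc
from .expression_truth import (
    absolute_accuracy,
    cross_contamination_fraction,
    ercc_ratio_recovery,
    relative_accuracy,
)
from .io import (
    ContractError,
    MAQC_TYPES,
    MIXTURE_TYPES,
    QUARTET_TYPES,
    relative_expression,
    to_log2,
    write_expression_matrix,
    write_sample_sheet,
    write_truth_set,
)
from .mixing import fit_mixture_curve
from .normalization import size_factors_tmm
from .pvca import PvcaConfig, run_pvca
from .qc import evaluate_flags
from .simulate import SimulationConfig, simulate_panel
from .snr import compute_snr, filter_genes_detected, leave_one_out_snr

__all__ = ["RunManifest", "PipelineError", "run_full_assessment"]

QUARTET_AND_MIX = QUARTET_TYPES + MIXTURE_TYPES


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: list
    started: str
    finished: str = ""


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else str(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(obj.item(), ndigits)
    return obj


def run_full_assessment(config: dict | None = None, out_dir=None) -> tuple[RunManifest, dict]:
    """Run the stage graph on a simulated panel and aggregate a report.

    ``config`` may carry a ``simulation`` section (SimulationConfig fields)
    and per-stage toggles ``pvca``, ``deg``, ``mixing`` (booleans). Writes
    report.json plus the simulated tables when ``out_dir`` is given.
    """
    config = dict(config or {})
    sim_kwargs = dict(config.get("simulation", {}))
    sim_cfg = SimulationConfig(**sim_kwargs)
    enabled = {k: bool(config.get(k, True)) for k in ("pvca", "deg", "mixing")}
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    report: dict = {"config": {"simulation": dataclasses.asdict(sim_cfg)}}
    stage = "simulate"
    try:
        counts, fpkm, sheet, truth = simulate_panel(sim_cfg)
        log2m = to_log2(fpkm)
        rel = relative_expression(log2m, sheet, reference_type="D6")

        stage = "normalize"
        tmm = size_factors_tmm(counts.subset(samples=sheet.libraries(lab_id=sheet.labs[0])))
        report["normalization"] = {
            "tmm_factors_lab1": {k: float(v) for k, v in tmm.factors.items()}
        }

        stage = "snr"
        detected = filter_genes_detected(counts)
        human = [g for g in detected.gene_ids if g not in set(truth.ercc.ids)]
        log2_detected = log2m.subset(genes=human)
        snr_section = {}
        for lab in sheet.labs:
            libs = sheet.libraries(lab_id=lab)
            sub = log2_detected.subset(samples=libs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                snr_q = compute_snr(sub, sheet, QUARTET_AND_MIX)
                snr_m = compute_snr(sub, sheet, MAQC_TYPES)
                loo = leave_one_out_snr(sub, sheet, QUARTET_AND_MIX)
            snr_section[lab] = {
                "snr18_quartet_mix": snr_q.snr_db,
                "snr6_maqc": snr_m.snr_db,
                "snr17_minus_snr18_max": loo.max_delta,
                "loo_outliers": loo.outliers,
            }
        report["snr"] = snr_section

        stage = "expression_truth"
        lab1 = sheet.labs[0]
        lab1_libs = sheet.libraries(lab_id=lab1)
        baseline_truth = truth.baseline_log2
        abs_rep = absolute_accuracy(
            log2_detected.subset(samples=sheet.libraries(lab_id=lab1, sample_type="D6")),
            baseline_truth,
            label="lab1 D6 vs planted baseline",
        )
        rel_rep = relative_accuracy(
            rel.subset(samples=lab1_libs), truth.truth_sets["M8/D6"], sheet
        )
        ercc_rep = ercc_ratio_recovery(
            log2m.subset(samples=lab1_libs), sheet, truth.ercc
        )
        contam = cross_contamination_fraction(counts, sheet, truth.ercc.ids)
        report["expression_accuracy"] = {
            "absolute": {"pearson_r": abs_rep.pearson_r, "rmse": abs_rep.rmse,
                         "n_genes": abs_rep.n_genes},
            "relative_m8_d6": {"pearson_r": rel_rep.pearson_r, "rmse": rel_rep.rmse,
                               "n_genes": rel_rep.n_genes},
            "ercc_ratio": {"pearson_r": ercc_rep.pearson_r, "rmse": ercc_rep.rmse},
            "max_cross_contamination_fraction": float(contam.max()) if len(contam) else 0.0,
        }

        if enabled["mixing"]:
            stage = "mixing"
            rel_lab = rel.subset(samples=lab1_libs)
            type_of = sheet.sample_type_of()
            mix_section = {}
            for which in MIXTURE_TYPES:
                m8_cols = [s for s in rel_lab.sample_ids if type_of[s] == "M8"]
                mix_cols = [s for s in rel_lab.sample_ids if type_of[s] == which]
                x = rel_lab.data[m8_cols].mean(axis=1).loc[human].to_numpy()
                y = rel_lab.data[mix_cols].mean(axis=1).loc[human].to_numpy()
                fit = fit_mixture_curve(x, y, which, mode=sim_cfg.mixture_mode)
                mix_section[which] = {
                    "z_fitted": fit.z, "rmse_at_reference_z": fit.rmse,
                    "n_genes": fit.n_genes,
                }
            report["mixing"] = mix_section

        if enabled["deg"]:
            stage = "deg"
            deg_section = {}
            for comparison in ("M8/D6", "MAQC_A/MAQC_B"):
                calls = internal_deg_caller(
                    log2_detected, sheet, comparison, lab_id=lab1
                )
                ct = classify_calls(truth.truth_sets[comparison], calls)
                deg_section[comparison] = {
                    "mcc": mcc(ct),
                    "auc": ranking_auc(truth.truth_sets[comparison], calls),
                    "tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn,
                }
            report["deg"] = deg_section

        if enabled["pvca"]:
            stage = "pvca"
            factors = [f for f in sheet.factor_names]
            pvca_cfg = PvcaConfig(factors=factors)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                quartet_libs = sheet.libraries(sample_types=QUARTET_TYPES)
                vd_q = run_pvca(log2_detected.subset(samples=quartet_libs), sheet, pvca_cfg)
                maqc_libs = sheet.libraries(sample_types=MAQC_TYPES)
                vd_m = run_pvca(log2_detected.subset(samples=maqc_libs), sheet, pvca_cfg)
            report["pvca"] = {
                "quartet": {k: float(v) for k, v in vd_q.proportions.items()},
                "quartet_technical": vd_q.technical_proportion(),
                "quartet_biological": vd_q.biological_proportion(),
                "maqc": {k: float(v) for k, v in vd_m.proportions.items()},
                "maqc_technical": vd_m.technical_proportion(),
                "maqc_biological": vd_m.biological_proportion(),
            }

        stage = "qc_flags"
        qc_rows = []
        for lab in sheet.labs:
            lab_contam = contam[[s for s in contam.index if s.startswith(f"{lab}_")]]
            qc_rows.append(
                {
                    "lab_id": lab,
                    "snr_maqc": snr_section[lab]["snr6_maqc"],
                    "snr_quartet": snr_section[lab]["snr18_quartet_mix"],
                    "snr17_minus_snr18_max": snr_section[lab]["snr17_minus_snr18_max"],
                    "ercc_cross_contam_max_pct": float(lab_contam.max() * 100)
                    if len(lab_contam)
                    else 0.0,
                    "identity_check_pass": True,
                }
            )
        flags = evaluate_flags(pd.DataFrame(qc_rows))
        report["qc_flags"] = {
            lab: row.to_dict() for lab, row in flags.table.iterrows()
        }
    except ContractError as exc:
        raise PipelineError(stage, exc) from exc

    outputs = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression_matrix(counts, out / "counts.tsv")
        write_expression_matrix(fpkm, out / "fpkm.tsv")
        write_sample_sheet(sheet, out / "samplesheet.tsv")
        for name, ts in truth.truth_sets.items():
            path = out / f"truth_{name.replace('/', '_vs_')}.tsv"
            write_truth_set(ts, path)
            outputs.append(str(path))
        truth.ercc.data.to_csv(out / "ercc_truth.tsv", sep="\t")
        outputs += [str(out / n) for n in ("counts.tsv", "fpkm.tsv", "samplesheet.tsv",
                                           "ercc_truth.tsv")]
        report_path = out / "report.json"
        report_path.write_text(json.dumps(_round_floats(report), indent=2, sort_keys=True))
        outputs.append(str(report_path))

    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=sim_cfg.seed,
        version=__version__,
        outputs=outputs,
        started=started,
        finished=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    return manifest, _round_floats(report)
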