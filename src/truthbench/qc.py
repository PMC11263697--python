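"""Multi-metric quality flagging of laboratory datasets.

Pre-alignment, post-alignment and sample-level metrics are compared against
fixed thresholds with strict inequalities; a laboratory passes only if every
assessed criterion passes. Metrics that were not supplied are reported as
"unassessed" and do not fail a laboratory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContractError

__all__ = ["QC_CRITERIA", "QcFlagReport", "evaluate_flags"]


def _gt(threshold):
    return lambda v: v > threshold


def _lt(threshold):
    return lambda v: v < threshold


#: criterion name -> (metric column, predicate, human-readable rule)
QC_CRITERIA = {
    "q30": ("q30_pct", _gt(85.0), "Q30 > 85%"),
    "read_pairs": ("n_read_pairs_millions", _gt(20.0), "paired reads > 20 M"),
    "duplication": ("duplication_pct", _lt(30.0), "duplication rate < 30%"),
    "mapping": ("mapping_pct", _gt(90.0), "total mapping rate > 90%"),
    "bias_5to3": ("bias_5to3", lambda v: 0.8 < v < 1.2, "5'-3' bias in (0.8, 1.2)"),
    "intergenic": ("intergenic_pct", _lt(10.0), "intergenic reads < 10%"),
    "snr_maqc": ("snr_maqc", _gt(20.0), "SNR (MAQC samples) > 20"),
    "snr_quartet": ("snr_quartet", _gt(12.0), "SNR (Quartet samples) > 12"),
    "snr17_delta": ("snr17_minus_snr18_max", _lt(6.0), "max(SNR17 - SNR18) < 6"),
    "ercc_contamination": (
        "ercc_cross_contam_max_pct",
        _lt(0.005),
        "ERCC reads in spike-in-free samples < 0.005%",
    ),
    "identity_check": ("identity_check_pass", lambda v: bool(v), "SNP identity check passes"),
}

_PERCENT_COLUMNS = ("q30_pct", "duplication_pct", "mapping_pct", "intergenic_pct")


@dataclass
class QcFlagReport:
    table: pd.DataFrame  # index lab_id; per-criterion pass/fail/unassessed + final

    @property
    def passing_labs(self) -> list:
        return self.table.index[self.table["final"] == "pass"].tolist()


def evaluate_flags(metrics: pd.DataFrame, strict: bool = True) -> QcFlagReport:
    """Apply the quality decision table to per-lab metric rows.

    ``metrics`` must have a ``lab_id`` column (or lab ids as index); missing
    or NaN metric values leave a criterion "unassessed". With
    ``strict=False`` boundary values pass instead of failing.
    """
    df = metrics.copy()
    if "lab_id" in df.columns:
        df = df.set_index("lab_id")
    for col in _PERCENT_COLUMNS:
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ContractError(f"{col} outside [0, 100]")
    if "bias_5to3" in df.columns and (df["bias_5to3"].dropna() <= 0).any():
        raise ContractError("bias_5to3 must be positive")

    out = {}
    for name, (col, pred, _rule) in QC_CRITERIA.items():
        if col not in df.columns:
            out[name] = pd.Series("unassessed", index=df.index)
            continue
        results = []
        for v in df[col]:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                results.append("unassessed")
            else:
                ok = pred(v)
                if not strict and not ok and col != "identity_check_pass":
                    # relaxed mode: boundary equality passes
                    threshold_hit = any(
                        np.isclose(v, t)
                        for t in (85.0, 20.0, 30.0, 90.0, 0.8, 1.2, 10.0, 12.0, 6.0, 0.005)
                    )
                    ok = ok or threshold_hit
                results.append("pass" if ok else "fail")
        out[name] = pd.Series(results, index=df.index)
    table = pd.DataFrame(out)
    table["final"] = np.where((table == "fail").any(axis=1), "fail", "pass")
    return QcFlagReport(table)
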