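"""Penalized DEG evaluation: confusion classification, MCC, AUC, the
truth-labeling rule, the internal caller and the filtering sweep."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_group_matrix
from truthbench.deg import (
    ConfusionTable,
    FilterSpec,
    classify_calls,
    filter_sweep,
    internal_deg_caller,
    label_truth_taqman_rule,
    mcc,
    optimal_thresholds,
    ranking_auc,
)
from truthbench.io import ContractError, DegCallTable, ExpressionMatrix, TruthSet


def _truth(labels, fcs=None, genes=None, comparison="M8/D6"):
    genes = genes or [f"g{i}" for i in range(len(labels))]
    if fcs is None:
        fcs = [1.0 if l == "up" else -1.0 if l == "down" else 0.0 for l in labels]
    return TruthSet(
        comparison,
        pd.DataFrame({"expected_log2fc": fcs, "deg_label": labels}, index=genes),
    )


def _calls(calls, ps=None, genes=None, comparison="M8/D6"):
    genes = genes or [f"g{i}" for i in range(len(calls))]
    ps = ps if ps is not None else [0.01 if c != "not_de" else 0.5 for c in calls]
    fcs = [1.0 if c == "up" else -1.0 if c == "down" else 0.0 for c in calls]
    return DegCallTable(
        comparison,
        pd.DataFrame({"log2fc": fcs, "p": ps, "call": calls}, index=genes),
    )


class TestTaqmanRule:
    def test_strong_fold_change_called_with_direction(self, rng):
        genes = ["g0", "g1"]
        a = pd.DataFrame(rng.normal(0, 0.01, (2, 3)) + [[2.0], [-2.0]], index=genes)
        b = pd.DataFrame(rng.normal(0, 0.01, (2, 3)), index=genes)
        truth = label_truth_taqman_rule(a, b, "M8/D6")
        assert truth.data["deg_label"].tolist() == ["up", "down"]

    def test_significant_but_small_fc_is_non_de(self, rng):
        genes = ["g0"]
        a = pd.DataFrame(rng.normal(0.58, 1e-6, (1, 4)), index=genes)  # FC ~ 1.5
        b = pd.DataFrame(rng.normal(0.0, 1e-6, (1, 4)), index=genes)
        truth = label_truth_taqman_rule(a, b, "M8/D6")
        assert truth.data["deg_label"].iloc[0] == "non_de"

    def test_null_type_one_error_near_alpha(self, rng):
        n = 4000
        a = pd.DataFrame(rng.normal(0, 1, (n, 3)), index=range(n))
        b = pd.DataFrame(rng.normal(0, 1, (n, 3)), index=range(n))
        from truthbench.deg import _two_group_t

        _, p = _two_group_t(a.to_numpy(), b.to_numpy(), equal_var=True)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.015)


class TestClassifyCalls:
    def test_perfect_calls(self):
        truth = _truth(["up", "down", "non_de", "non_de"])
        calls = _calls(["up", "down", "not_de", "not_de"])
        ct = classify_calls(truth, calls)
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (2, 2, 0, 0)

    def test_empty_call_table_penalizes_all_truth_degs(self):
        truth = _truth(["up", "down", "up", "non_de"])
        calls = DegCallTable(
            "M8/D6", pd.DataFrame(columns=["log2fc", "p", "call"]).astype(
                {"log2fc": float, "p": float, "call": str}
            )
        )
        ct = classify_calls(truth, calls)
        assert ct.tp == 0 and ct.fp == 0
        assert ct.fn == 3 == ct.n_unreported_truth_positives
        assert ct.tn == 1

    def test_opposite_direction_counts_once_conserving_totals(self):
        truth = _truth(["up", "non_de"])
        calls = _calls(["down", "not_de"])
        ct = classify_calls(truth, calls)
        assert ct.fn == 1 and ct.fp == 0 and ct.n_direction_errors == 1
        assert ct.total == 2
        ct_fp = classify_calls(truth, calls, opposite_direction="fp")
        assert ct_fp.fp == 1 and ct_fp.fn == 0 and ct_fp.total == 2

    def test_randomized_calls_match_brute_force_tabulation(self, rng):
        n = 1000
        labels = rng.choice(["up", "down", "non_de"], n, p=[0.15, 0.15, 0.7])
        truth = _truth(labels)
        reported = rng.random(n) < 0.8
        call_labels = rng.choice(["up", "down", "not_de"], n)
        genes = [f"g{i}" for i in range(n)]
        keep = [g for g, r in zip(genes, reported) if r]
        calls = _calls(
            [c for c, r in zip(call_labels, reported) if r], genes=keep
        )
        ct = classify_calls(truth, calls)

        tp = tn = fp = fn = 0
        call_of = dict(zip(keep, (c for c, r in zip(call_labels, reported) if r)))
        for g, lab in zip(genes, labels):
            c = call_of.get(g, "absent")
            if lab in ("up", "down"):
                if c == lab:
                    tp += 1
                else:
                    fn += 1
            else:
                if c in ("up", "down"):
                    fp += 1
                else:
                    tn += 1
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (tp, tn, fp, fn)
        assert ct.total == n


class TestMcc:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((10, 10, 0, 0), 1.0),
            ((0, 0, 10, 10), -1.0),
            ((5, 90, 2, 3), 444 / math.sqrt(7 * 8 * 92 * 93)),
            ((0, 0, 0, 0), 0.0),
            ((3, 0, 0, 5), 0.0),  # zero denominator factor
        ],
    )
    def test_values(self, cells, expected):
        tp, tn, fp, fn = cells
        assert mcc(ConfusionTable(tp=tp, tn=tn, fp=fp, fn=fn)) == pytest.approx(expected)

    def test_label_flip_antisymmetry(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            a = mcc(ConfusionTable(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn)))
            b = mcc(ConfusionTable(tp=int(fp), tn=int(fn), fp=int(tp), fn=int(tn)))
            assert a == pytest.approx(-b)


class TestRankingAuc:
    def test_perfect_separation(self):
        truth = _truth(["up", "up", "non_de", "non_de"])
        calls = _calls(["up", "up", "not_de", "not_de"], ps=[1e-8, 1e-7, 0.3, 0.6])
        assert ranking_auc(truth, calls) == 1.0

    def test_all_ties_give_half(self):
        truth = _truth(["up", "non_de", "up", "non_de"])
        calls = _calls(["up", "up", "up", "up"], ps=[0.01] * 4)
        assert ranking_auc(truth, calls) == 0.5

    def test_shuffled_labels_near_half(self, rng):
        n = 4000
        labels = rng.permutation(["up"] * 1000 + ["non_de"] * 3000)
        truth = _truth(labels)
        calls = _calls(["up"] * n, ps=rng.random(n))
        assert ranking_auc(truth, calls) == pytest.approx(0.5, abs=0.03)

    def test_unreported_genes_get_worst_rank(self):
        truth = _truth(["up", "up", "non_de", "non_de"])
        calls = _calls(["up", "not_de"], ps=[0.001, 0.8], genes=["g0", "g2"])
        # g1 (truth DEG, unreported) ranked below the reported g2
        auc_worst = ranking_auc(truth, calls, unreported="worst")
        auc_drop = ranking_auc(truth, calls, unreported="drop")
        assert auc_worst < auc_drop


class TestInternalCaller:
    def test_recovers_strong_planted_degs(self, rng):
        matrix, sheet = make_group_matrix(
            rng, n_genes=100, groups=["M8", "D6"], replicates=4, group_sd=0.0,
            noise_sd=0.1,
        )
        planted = matrix.gene_ids[:10]
        m8_cols = sheet.libraries(sample_type="M8")
        matrix.data.loc[planted, m8_cols] += 3.0
        calls = internal_deg_caller(matrix, sheet, "M8/D6")
        assert (calls.data.loc[planted, "call"] == "up").all()
        assert (calls.data.drop(planted)["call"] == "not_de").mean() > 0.9

    def test_alpha_zero_calls_nothing(self, rng):
        matrix, sheet = make_group_matrix(rng, n_genes=50, groups=["M8", "D6"])
        calls = internal_deg_caller(matrix, sheet, "M8/D6", alpha=0.0)
        assert (calls.data["call"] == "not_de").all()

    def test_recentering_removes_composition_offset(self, rng):
        matrix, sheet = make_group_matrix(
            rng, n_genes=200, groups=["M8", "D6"], replicates=4, group_sd=0.0,
            noise_sd=0.05,
        )
        # a global shift of the M8 columns mimics composition bias
        matrix.data[sheet.libraries(sample_type="M8")] += 1.2
        calls = internal_deg_caller(matrix, sheet, "M8/D6", recenter=True)
        assert (calls.data["call"] == "not_de").all()
        raw = internal_deg_caller(matrix, sheet, "M8/D6", recenter=False)
        assert (raw.data["call"] != "not_de").any()


class TestFilterSweep:
    def test_zero_threshold_equals_unfiltered(self, small_panel):
        cfg, counts, fpkm, sheet, truth = small_panel
        human = [g for g in counts.gene_ids if not g.startswith("SPIKEIN")]
        comparison = "MAQC_A/MAQC_B"
        sweep = filter_sweep(
            counts.subset(genes=human), sheet, comparison,
            truth.truth_sets[comparison],
            specs=[FilterSpec("max", "counts")], thresholds=(0,),
            ann=truth.annotation, lab_id="lab01",
        )
        unfiltered = filter_sweep(
            counts.subset(genes=human), sheet, comparison,
            truth.truth_sets[comparison], specs=[],
            ann=truth.annotation, lab_id="lab01",
        )
        assert sweep["n_deg"].iloc[0] == unfiltered["n_deg"].iloc[0]
        assert sweep["tpr"].iloc[0] == pytest.approx(unfiltered["tpr"].iloc[0])

    def test_toy_percentile_removes_exactly_the_zero_genes(self, rng):
        matrix, sheet = make_group_matrix(
            rng, n_genes=10, groups=["M8", "D6"], replicates=3
        )
        counts_df = np.round(2.0 ** (matrix.data + 4)).astype(int)
        counts_df.iloc[6:] = 0  # four all-zero genes
        counts = ExpressionMatrix(counts_df, "counts")
        truth = _truth(["non_de"] * 10, genes=matrix.gene_ids.tolist())
        sweep = filter_sweep(
            counts, sheet, "M8/D6", truth,
            specs=[FilterSpec("max", "counts")], thresholds=(40,),
        )
        assert sweep["n_kept"].iloc[0] == 6

    def test_threshold_above_70_rejected(self, rng):
        matrix, sheet = make_group_matrix(rng, n_genes=10, groups=["M8", "D6"])
        counts = ExpressionMatrix(
            np.round(2.0 ** (matrix.data + 4)).astype(int), "counts"
        )
        truth = _truth(["non_de"] * 10, genes=matrix.gene_ids.tolist())
        with pytest.raises(ContractError):
            filter_sweep(counts, sheet, "M8/D6", truth,
                         specs=[FilterSpec("max", "counts")], thresholds=(80,))

    def test_argmax_tpr_matches_argmax_ndeg_tpr(self, small_panel):
        """The practical threshold rule (max #DEG) yields nearly the same
        sensitivity as the oracle rule (max TPR)."""
        cfg, counts, fpkm, sheet, truth = small_panel
        human = [g for g in counts.gene_ids if not g.startswith("SPIKEIN")]
        comparison = "MAQC_A/MAQC_B"
        sweep = filter_sweep(
            counts.subset(genes=human), sheet, comparison,
            truth.truth_sets[comparison], ann=truth.annotation, lab_id="lab01",
        )
        opt = optimal_thresholds(sweep)
        gap = (opt["tpr_at_argmax_tpr"] - opt["tpr_at_argmax_ndeg"]).abs()
        assert (gap <= 0.05).all()
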