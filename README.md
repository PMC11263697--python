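# truthbench

Multi-ground-truth performance assessment for multi-laboratory RNA-seq.

When many laboratories profile the same reference samples with their own
protocols and pipelines, how do you tell good expression data from bad —
especially for the *subtle* differential expression that matters clinically?
`truthbench` implements the assessment toolkit built around a reference
panel with several kinds of planted truth:

- **Quartet-style samples** (M8, F7, D5, D6): four related reference RNAs
  with small inter-sample differences; D6 serves as the control.
- **MAQC-style samples** (A, B): two reference RNAs with large differences.
- **Titration mixtures** T1 and T2: M8 and D6 mixed 3:1 and 1:3, so every
  gene's expected expression is a known function of its parents.
- **ERCC-style spike-ins**: 92 synthetic controls in two mixes whose
  subgroup concentration ratios (4:1, 1:2, 2:3, 1:1) are built-in truth.

## What it computes

**Data quality — PCA-based SNR.** Genes are scaled to unit variance, samples
are projected onto the first two principal components weighted by their
explained-variance fractions `f1, f2`, and

```
SNR = 10 · log10( mean squared distance between group centroids
                / mean squared replicate-to-centroid distance )   [dB]
```

A leave-one-out variant (SNR17 vs SNR18) flags a replicate as a random
failure when its removal raises the SNR by more than 6 dB.

**Expression accuracy.** Pearson r and RMSE of log2(FPKM + 0.01) values
against reference quantifications, of D6-centered relative expression
against expected log2 fold changes, and of observed spike-in M8/D6 ratios
against the subgroup design, stratified by concentration.

**Titration built-in truth.** Because the parents' mRNA fractions differ,
the mixing weights are corrected by a shift coefficient z (k1 = z/(z+3),
k2 = 3z/(3z+1); calibrated values 0.974 for T1 and 0.949 for T2). The
package evaluates the expected curves, estimates z per gene in closed form,
and fits the titration curve robustly (Tukey-biweight IRLS) to score how
well a laboratory recovers the known mixing ratios.

**DEG accuracy — penalized MCC.** Submitted call tables are scored against
truth with truth DEGs *absent* from a submission counted as false negatives;
the Matthews correlation coefficient

```
MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

summarizes the confusion table, alongside a −log10(p) ranking AUC and a
low-expression filtering sweep (six filter statistics × percentile
thresholds, reporting TPR/precision and the argmax thresholds).

**Sources of variation — PVCA.** Per retained principal component, a
variance-components model with one random effect per experimental factor is
fitted by EM-REML (Aitken-accelerated); components are averaged with
eigenvalue weights and normalized into variance-source proportions.

**QC flagging.** The strict-inequality decision table (Q30 > 85%, reads
> 20 M, duplication < 30%, mapping > 90%, 5'–3' bias in (0.8, 1.2),
intergenic < 10%, SNR thresholds, spike-in cross-contamination < 0.005%,
identity check) with unassessed metrics never failing a laboratory.

**Synthetic panel generator.** A negative-binomial multi-laboratory
simulator of the full 8-type × 3-replicate × L-lab design — planted
sample-type effects, titration mixtures at a true z, spike-ins, per-protocol
factor effects, batch effects and replicate noise — that emits matching
truth tables, so the whole framework is testable without any downloads.

## Worked example

```python
import truthbench as tb
from truthbench.pvca import PvcaConfig, run_pvca

cfg = tb.SimulationConfig(n_genes=2000, n_labs=3, seed=7)
counts, fpkm, sheet, truth = tb.simulate_panel(cfg)
log2 = tb.to_log2(fpkm)
human = [g for g in log2.gene_ids if not g.startswith("SPIKEIN")]

libs = sheet.libraries(lab_id="lab01")
sub = log2.subset(genes=human, samples=libs)
snr_subtle = tb.compute_snr(sub, sheet, ["M8", "F7", "D5", "D6", "T1", "T2"])
snr_large = tb.compute_snr(sub, sheet, ["MAQC_A", "MAQC_B"])
print(f"SNR (Quartet + mixtures, 18 libraries): {snr_subtle.snr_db:.1f} dB")
print(f"SNR (MAQC pair, 6 libraries):           {snr_large.snr_db:.1f} dB")

rel = tb.relative_expression(log2.subset(samples=libs), sheet.subset(libs))
rep = tb.relative_accuracy(rel.subset(genes=human), truth.truth_sets["M8/D6"], sheet)
print(f"M8/D6 relative expression vs truth: r = {rep.pearson_r:.3f}, "
      f"RMSE = {rep.rmse:.3f} ({rep.n_genes} genes)")

t = sheet.sample_type_of()
x = rel.data.loc[human, [s for s in libs if t[s] == "M8"]].mean(axis=1)
y = rel.data.loc[human, [s for s in libs if t[s] == "T1"]].mean(axis=1)
fit = tb.fit_mixture_curve(x.to_numpy(), y.to_numpy(), "T1")
print(f"T1 titration fit: z = {fit.z:.3f} (calibrated 0.974), "
      f"RMSE vs expected curve = {fit.rmse:.3f}")

calls = tb.internal_deg_caller(log2.subset(genes=human), sheet,
                               "MAQC_A/MAQC_B", lab_id="lab01")
ct = tb.classify_calls(truth.truth_sets["MAQC_A/MAQC_B"], calls)
print(f"MAQC_A/MAQC_B DEG calls: TP={ct.tp} FP={ct.fp} FN={ct.fn} TN={ct.tn}, "
      f"MCC = {tb.mcc(ct):.3f}")
```

Output for this seed:

```
SNR (Quartet + mixtures, 18 libraries): 8.0 dB
SNR (MAQC pair, 6 libraries):           37.4 dB
M8/D6 relative expression vs truth: r = 0.373, RMSE = 0.496 (2000 genes)
T1 titration fit: z = 1.044 (calibrated 0.974), RMSE vs expected curve = 0.378
MAQC_A/MAQC_B DEG calls: TP=677 FP=7 FN=323 TN=993, MCC = 0.706
```

Reading it: the same laboratory that separates the large-difference pair
cleanly (37.4 dB) struggles to separate the subtle-difference panel from its
own replicate noise (8.0 dB); relative expression correlates only weakly
with the planted subtle fold changes, while the mixture fit still recovers a
z near its calibrated value; and large-difference DEG calling is accurate
(MCC 0.71) with the misses concentrated in modest fold changes. With only
three simulated laboratories the protocol factors are partially confounded,
which the PVCA module detects and reports as aliasing.

There is also a CLI mirroring the library surface:

```sh
truthbench simulate --config sim.yaml --out-dir panel/
truthbench snr --log2 log2.tsv --sheet panel/samplesheet.tsv \
               --groups M8,F7,D5,D6,T1,T2 --loo
truthbench eval-deg --truth panel/truth_M8_vs_D6.tsv --calls calls.tsv
truthbench run-all --config sim.yaml --out-dir run/
```

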