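# sgekit

Analysis toolkit for **saturation genome editing (SGE)** variant-function
experiments, in which a CRISPR/Cas9-mediated knock-in library introduces
every possible variant across a target region (all 64 codons at saturated
residues, or every SNV across an exon) and each variant's effect on cell
fitness and chemotherapeutic drug response is read out by amplicon
sequencing at an early (day 3) and a late (day 14) time point, under DMSO
and under cisplatin/olaparib selection. The package is written for
groups running such multiplexed assays of variant effect (MAVE) on DNA
repair genes such as *BRCA2*, where the output feeds clinical variant
interpretation (ACMG PS3/BS3 functional evidence).

## What it computes

Starting from paired FASTQ reads or a per-variant count table, with two
replicates per arm:

1. **HDR-gated variant calling** — mate pairs are overlap-merged, globally
   aligned to the reference amplicon (Needleman–Wunsch), and a read is
   counted for a library variant only if it carries the fixed synonymous
   PAM-marker edit (proof of template-directed repair), has no indels, and
   has no substitutions outside the saturated region. NHEJ indels are
   tallied into a per-(size, offset-from-cut) spectrum.
2. **Function scores** — with a pseudocount of 1 and per-sample totals as
   denominators, the function score of variant *v* in arm *a* is

   `FS_a(v) = log2( f_day14,a(v) / f_day3(v) )`,

   averaged over replicates; low-representation and replicate-discordant
   variants are filtered.
3. **Positional-bias normalization** (SNV-saturation path) — a weighted
   global post/pre ratio (weights 0.4 DMSO / 0.25 cisplatin / 0.25
   olaparib, normalized by their sum), a loess fit of log2 ratio against
   position on near-neutral variants only, subtraction of the fitted
   trend, and per-exon affine anchoring so every exon's synonymous and
   nonsense score medians match the global control medians.
4. **Classification** —
   * a three-variable linear **probit** model trained on synonymous and
     nonsense internal controls gives each variant a probability of
     impact on function, `PIF = Φ(β₀ + β·FS)`; `PIF ≤ 0.05` is functional,
     `PIF > 0.99` non-functional, between is intermediate. K-fold
     cross-validation and perturbation-based percentile 95% CIs
     (10,000 refits under Normal(0, 0.05) training noise) quantify
     robustness;
   * a class-conditional **Gaussian mixture** on the single normalized
     score gives a posterior probability of pathogenicity,
     `P(path | s) = π₋ φ₋(s) / (π₋ φ₋(s) + π₊ φ₊(s))`, with the same
     0.05/0.99 three-way rule, plus sensitivity/specificity, LR+/LR−,
     ROC/AUC and **OddsPath** mapped to ACMG PS3/BS3 evidence bands.
5. **Synthetic experiments** — `sgekit.simulate` generates fully
   ground-truthed count tables and overlapping paired FASTQ (HDR rates,
   indel spectra, bimodal effect structure, drug-sensitive hypomorphs,
   positional bias), so the entire pipeline is testable end to end with
   no external data.

## Worked example

`examples/03_function_scores_and_pif.py` simulates a six-codon
saturation experiment at assay-realistic conditions (2×10⁶ reads/sample,
1% HDR, −3 log2 dropout for loss-of-function variants) and runs the
probit path:

```
training controls: 15 synonymous, 18 nonsense
model-fit accuracy: 100%  (separation-stabilized fit: True)
K=5 cross-validation: accuracy 100.0%, sensitivity 100.0%, specificity 100.0%
PIF categories: {'functional': 195, 'non_functional': 164, 'intermediate': 19}
against ground truth (non-hypomorphs, n=358): sensitivity 100.0%, specificity 100.0%
```

The controls separate cleanly (hence the stabilized fit), every control is
recovered, and only variants near the decision thresholds stay
intermediate. `examples/04_snv_saturation_gmm.py` runs the exon-wide SNV
path with an injected positional editing bias of 0.4 log2 units:

```
neutral-variant mean log2 ratio after loess correction: +0.017 (injected bias amplitude was 0.4)
control-set sensitivity 100.0%, specificity 100.0%
LR+ inf, LR- 0.00, AUC 1.000
OddsPath pathogenic 561.00 (PS3_very_strong), benign 0.036 (BS3_strong)
```

The bias is removed to ~0.02 log2 units and the mixture classifier's
calibration metrics are printed on the control set.

A thin CLI mirrors the library (`sgekit simulate | call | score |
normalize | classify-pif | classify-gmm | report | run-all`); every run
logs the package version, seed and a config hash, and is bit-reproducible
under a fixed seed.

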