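# Methods

This note documents the models, conventions and numerical choices behind
`sgekit`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, which knobs matter, and what the
synthetic-data tests do and do not demonstrate.

## The assay being modelled

A saturation-genome-editing experiment knocks a variant library into a
single genomic amplicon by Cas9 cutting plus single-stranded
oligonucleotide repair. Every repair template carries one library variant
plus a fixed synonymous PAM-blocking edit (the *HDR marker*), so a
sequencing read can be attributed to the library only when the marker is
present. Cells are sampled at day 3 (library representation established,
dropout not yet complete) and day 14, after growth under DMSO, cisplatin
or olaparib, two independent replicates per arm. Loss-of-function
variants deplete in every arm; hypomorphs (partial function) survive DMSO
but deplete under DNA-damaging drugs; functional variants track wild
type. Observed HDR fractions are small (0.3–2.3% of reads) against a
background of unedited reads and NHEJ indels concentrated at the cut
site; out-of-frame indels act as additional loss-of-function controls.

## Read calling

* **Merging.** Mates are overlap-merged by scanning every overlap length
  ≥ `min_overlap` (default 10) and taking the lowest mismatch fraction
  (ties: longest overlap), subject to `max_mismatch_frac` (default 0.25);
  disagreeing bases resolve to the higher base quality.
* **Alignment.** Global Needleman–Wunsch with linear gap costs; defaults
  match +2, mismatch −1, **gap −6**. The steep gap penalty is
  deliberate: with a mild gap cost, a degenerate-codon replacement of up
  to three adjacent bases can align as a cheaper delete-plus-insert, and
  the read would then be misfiled as an NHEJ indel instead of a library
  variant — fatal for HDR-gated counting. Any gap milder than about −5
  admits such alignments; −6 keeps substitution alignments optimal for
  codon swaps while genuine length differences still force gaps.
  Traceback tie-breaking is fixed (diagonal, then gap-in-read, then
  gap-in-reference) so alignments are reproducible.
* **Classification.** Reads containing `N` are removed before alignment.
  A gapped alignment is recorded as an indel with the *net* signed size
  over all gap runs — net size is invariant to how an ambiguous indel is
  split and determines the reading frame — at the offset of the leftmost
  (left-aligned) gap edge from the cut. Ungapped reads are `WT` (no
  differences), `HDR_variant` (all marker edits present; all remaining
  substitutions inside the target region; the marker-only read maps to
  the wild-type-codon key `c.=`, a legitimate member of the NNN library),
  or `rejected_other`. Reads scoring below 0.6 of the perfect alignment
  score are excluded from per-sample totals as alignment failures; totals
  otherwise count every aligned read.

## Scores and filters

Frequencies are `(count + 1) / total aligned reads` per sample — the
pseudocount guarantees finite log ratios; the denominator is always the
per-sample total, never the sum over variants. The function score per
arm is the log2 day-14/day-3 frequency ratio, averaged over replicates
(each day-14 replicate is compared with its own day-3 replicate; day 3 is
the common denominator for all three arms).

Filters, each a documented boundary choice:

* codon path: keep requires day-3 frequency **strictly above** 1e-5 in
  *every* replicate (the boundary value is excluded);
* SNV path: additionally a raw day-3 count floor of 10, and removal of
  variants whose DMSO replicate post/pre ratios differ by more than
  2-fold **and** whose per-replicate class calls diverge, or that show
  the same two-part discordance in two or more conditions. "Differ by
  more than 2" is read as a fold change (max/min of the replicate
  ratios), because post/pre ratios are multiplicative; an
  arithmetic-difference mode is available
  (`apply_exon13_filters(..., fold_change_mode=False)`). The
  preliminary per-replicate call compares each replicate's log2 ratio
  with the midpoint of the synonymous- and nonsense-control medians for
  that replicate/condition.

The SNV path's single score starts from the weighted mean of the
per-condition mean post/pre ratios (0.4 DMSO, 0.25 cisplatin, 0.25
olaparib, normalized by the 0.9 weight sum), taken in log2.

## Positional-bias correction and anchoring

Editing rates fall off with distance from the cut, tilting raw log2
ratios along the amplicon. The trend is fitted with tricube-weighted
local linear regression (lowess, span 0.75 by default) on *near-neutral*
variants only, so biological dropout does not bend the fit. Inclusion is
a 1.25-fold window (|Δlog2| ≤ log2 1.25) measured **relative to a
provisional neutral trend**, not relative to zero: the provisional trend
anchors on the main mode of the score distribution (found by KDE; the
neutral cluster is assumed to be the majority, which holds whenever most
library variants are tolerated), coarse-selects everything within one
log2 unit of that mode, and smooths it. Measuring the window against
zero would exclude neutral variants wherever the trend itself — or the
global renormalization shift that appears when lethal alleles leave the
day-14 pool — exceeds 0.32 log2 units, and the correction would fail
precisely where it is needed. A one-sided reading (ratio ≥ 1.25) is
available behind `one_sided=True`. Fewer than 10 eligible variants is an
error, not a silent fallback. Predictions clamp to the nearest fitted
value outside the fitted range.

Corrected scores are anchored per exon by the unique affine map sending
(exon synonymous median, exon nonsense median) onto the global control
medians; the map is monotone, so within-exon rankings never change, and
with a single exon it is the identity. Equal or inverted anchors raise a
degenerate-anchor error.

## Probit PIF classifier

Training set: synonymous controls (label 0) and nonsense controls
(label 1); predictors: the three per-arm function scores. PIF is
Φ(β₀ + β·FS). Because clean controls are typically linearly separable,
the unpenalized MLE diverges; the fit therefore falls back to a
quadratic-penalized (ridge, λ = 1e-4 on all coefficients) probit solved
by BFGS with an analytic gradient in log-Φ space. The plain statsmodels
fit is accepted only when it converges, stays below a coefficient bound,
*and* achieves at least the stabilized fit's unpenalized likelihood —
under quasi-separation Newton iterations can stall at poorly oriented
stationary points, which this check rejects. The `separation` flag
records which path was taken.

Categories: PIF ≤ 0.05 functional (closed boundary), PIF > 0.99
non-functional (open boundary), otherwise intermediate. Accuracy-type
metrics (model fit, cross-validation) use a 0.5 cutoff, since a
three-way rule has no single "correct assignment" threshold; this cutoff
is configurable. K-fold CV uses random unstratified folds differing in
size by at most one; overall accuracy is the unweighted mean of per-fold
accuracies; sensitivity/specificity average over the folds containing
the respective class. Per-variant 95% CIs come from refitting under
independent Normal(0, 0.05) perturbations of the *training* predictors
only (never the full-table predictors) and taking 2.5/97.5 percentiles;
failed refits are skipped and warned about above a 1% failure rate.

## Gaussian-mixture classifier

A supervised class-conditional model (model-based discriminant
analysis): per-class Gaussian mean and SD estimated from labelled
controls, unequal variances by default (`pooled_variance` available when
a class has too little spread), priors from training proportions
(`equal_priors` optional). The posterior probability of pathogenicity is
the non-functional component's responsibility, computed in log space.
Categories: posterior > 0.99 pathogenic, < 0.05 benign (both strict),
else intermediate.

Evaluation: sensitivity/specificity on the percent scale with
intermediates counted against their true class by default (conservative;
`exclude` mode available); LR+ = sens/(100−spec), LR− = (100−sens)/spec
with infinities flagged at the boundaries; ROC by threshold sweep with
trapezoidal AUC (equivalent to the Mann–Whitney statistic, which the
tests use as an independent oracle); OddsPath from the control
proportion P1 and small-count-corrected prediction proportions
P2 = n/(n+1), mapped to PS3/BS3 evidence bands at 2.1 / 4.3 / 18.7 / 350
and their reciprocals. Zero predicted-benign makes OddsPath_benign
infinite and is reported as such rather than masked.

## Synthetic-data generator

The generator emulates the experiment's statistical structure: day-3
allele frequencies split the read pool into wild type, an HDR fraction
(default 1%, configurable to the observed 0.3–2.3% range) shared across
library variants by a Dirichlet draw (concentration 50 — the published
day-3 abundance dispersion is not reported, so this is a package choice
giving replicate read-count correlations comparable to those observed),
and an NHEJ fraction (default 20%) spread over ~a dozen indel alleles
with geometric-tailed sizes and positions within a few bases of the cut.
Day-14 expected frequencies multiply day-3 frequencies by
2^(true log2FC + replicate noise + positional bias) and renormalize;
counts are multinomial at fixed depth (default 2×10⁶), so per-sample
totals are exact. True classes: synonymous and deep-intronic variants
are functional, nonsense and splice-region (±2 nt) variants
non-functional, missense variants follow a configurable mix (50%
functional / 45% non-functional / 5% hypomorph by default, matching the
roughly even functional/non-functional split such regions show).
Effects: functional N(0, 0.3), non-functional N(−3, 0.5) in every arm,
hypomorph N(0, 0.3) in DMSO and N(−2, 0.5) under drugs; out-of-frame
indel alleles are lethal (−3), in-frame neutral. Positional bias is a
smooth sinusoid on the log2 ratio with configurable amplitude.

Read-level simulation emits overlapping mate pairs covering each allele
from both ends, flat per-base error rate, optional `N`-contaminated
reads, and the true allele id in every read name. Indel alleles are
canonicalized through the caller itself (align the pure allele sequence,
record the size/offset the pipeline reports), so noiseless reads
round-trip to exactly the drawn counts even for alignment-ambiguous
insertions.

What passing tests on this generator do **not** show: PCR duplicates and
chimeras, quality-score structure, context-dependent error rates,
replicate-specific editing efficiency differences, and real biological
effect distributions (true effects are drawn from the configured
Gaussians, not from any empirical distribution). Classification
performance on simulated data is therefore an internal-consistency
check, not an estimate of accuracy on real libraries.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run six-codon (378-variant)
and one-exon (267-SNV) experiments at 2×10⁶ reads per sample for
count-level stages, and 1–2×10³ read pairs for read-level round-trips —
sizes chosen so the full pipeline, including alignment of every read, is
exercised in seconds while keeping per-variant day-3 coverage in the
range the assay itself achieves (tens to hundreds of reads). Every
source of randomness flows from a single integer seed through
`numpy.random.default_rng`; simulation stages derive independent child
streams from (seed, stage) pairs, so adding a stage never perturbs the
draws of another.

## Known limitations

* Single-amplicon scope: no liftover, no multi-amplicon designs; codons
  truncated by the amplicon boundary cannot be confirmed
  synonymous/nonsense and are annotated conservatively as missense with
  empty amino-acid fields.
* The loess inclusion rule assumes the neutral cluster is the modal one;
  a region where most variants are deleterious would need explicit
  control-based inclusion instead.
* The probit CV folds are unstratified by default; with very small
  control classes a fold can lack one class, in which case that fold
  contributes only to the metrics its classes support.
* Splice effects are handled as annotations (an external splice-score
  column with a strict 0.2 flag threshold), not predicted.
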