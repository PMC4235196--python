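# Methods

This note documents the models, parameter defaults, numerical choices and
limitations of `condop`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Breakpoint detection

Coverage depth is a dense per-base integer array for a single replicon
(1-based coordinates throughout; BED input is converted on read). A window
of length *w* = 100 nt slides with stride 1 and each depth segment *y* is
correlated with the step template *x* = [0₅₀, 1₅₀]. Significance uses the
exact two-sided correlation test, *t* = *r*·√((*n*−2)/(1−*r*²)) with
*n*−2 df; |*r*| = 1 maps to *p* = 0. Thresholds: *r* > 0.7 and *p* < 10⁻⁷
for increases, the mirror for decreases. The whole scan is computed with
cumulative sums plus one cross-correlation (O(*n·w*)); windows with zero
depth variance are skipped (the correlation is undefined there).

**Run merging.** Stride-1 scanning makes every true step produce a run of
consecutive significant windows. Maximal runs of same-sign significant
windows are merged; the reported breakpoint is the centre of the window with
maximal |*r*| (leftmost on ties), where "centre" is the first base of the
window's right half — for an ideal step `…a a b b…` the reported position is
the first base at depth *b*. A transcript's 3′ boundary (coverage drop from
the plateau to background) is therefore reported at *end* + 1.

**Detectability.** For a step from mean depth *a* to *b* under Poisson
noise, the expected aligned-window correlation is
*r* ≈ 1/√(1 + 2(*a*+*b*)/Δ², Δ = *b*−*a*; the *r* > 0.7 rule therefore
requires roughly Δ² > 2(*a*+*b*), i.e. a plateau of mean depth ≳ 3–4 reads
per base over a 0.2 background. Boundaries of more weakly expressed
transcripts are genuinely invisible to a 100-nt window and are the dominant
(small) loss term in boundary recall.

**Strandedness.** Strand-specific libraries are scanned per strand and
expression is computed on the matching strand's depth; unstranded libraries
use the combined track for genes of both strands. On the genomic axis a
coverage *decrease* is the transcription *start* of a minus-strand unit, and
all 5′/3′ logic downstream is mirrored accordingly.

## Expression and thresholds

Read counts are estimated from depth: C = Σdepth/ℓ_read over the feature,
N = total mapped bases/ℓ_read, RPKM = C/((L/1000)(N/10⁶)). Levels are
log₂(RPKM + 1); the +1 pseudocount keeps zero-coverage IGRs finite while
leaving expressed features essentially unchanged. The minimum-expression
thresholds are the 10th percentile (linear interpolation) of the CDS and
IGR log₂ distributions respectively; the IGR distribution is taken over the
intergenic regions of same-strand adjacent pairs, the universe the linkage
rules test.

## Confirmation and labelling

An operon start point must (i) change coverage more than 2-fold between the
window halves (computed as (mean_right+1)/(mean_left+1), inverted for
decreases), (ii) anchor the nearest downstream gene within 0–300 nt
(`max_utr`, generous for bacterial 5′UTRs and configurable), (iii) with that
gene expressed above the CDS threshold and (iv) a structural gene of a
reference operon. Anchoring at *any* member (not only the first gene)
supports condition-dependent internal starts; a `first_gene_only` flag
restores the stricter mode. Linkage walks the reference operon downstream
from the anchor and stops at the first violated rule; junctions with no IGR
(abutting or co-directionally overlapping genes) satisfy the IGR rules
vacuously — such overlap is itself strong operon evidence. No end point is
required after the last linked gene. At least 2 genes must link. When
several anchors confirm the same reference operon the longest confirmation
wins.

Pair labels are assigned in priority order OP → NOP → POP/EGP → unlabeled.
A confirmed junction that also contains a breakpoint (possible only through
edge-case chaining, since linkage rule 3 excludes it) stays OP with a logged
warning — confirmation uses more evidence. NOP deliberately does not require
expression of either gene. POP/EGP require *both* genes expressed.
Reference-co-operonic pairs may become NOP when a breakpoint splits them:
that is precisely the condition-dependent case the method targets.

## Features

`igrLength` is `start_{i+1} − end_i − 1` (negative = overlap). RSCU for
codon *c* of amino acid *a* is n_c·k_a/n_a; families absent from a gene get
RSCU 0, which keeps the codon-usage score total and symmetric. The score
sums the RSCU product over the 61 sense codons (bacterial code, table 11);
an amino-acid-level variant (family means first) is available via
`level="aa"`. For pairs without an IGR, `igrExpr` falls back to the minimum
of the two gene levels — a conservative stand-in chosen because overlap
implies co-transcription evidence at least as strong as either gene's level.

## Classifiers

* RF: 500-tree random forest on raw features (scale-invariant).
* NN: single hidden layer, H ∈ {2, 4, 6, 8}, L-BFGS, standardized inputs.
* SVM: RBF kernel, C ∈ {0.1, 1, 10, 100} × γ ∈ {0.01, 0.1, 1},
  standardized inputs.

NN/SVM hyperparameters are chosen on an internal stratified 25% validation
holdout of the training data and the winner is refit on the full training
table; standardization is fit on training folds only (no leakage). Class
imbalance is left untouched; the probability threshold is 0.5 and ROC uses
the continuous scores. Validation is a stratified 30% holdout plus 10×5
repeated stratified CV with fresh seeded folds per repeat; fold metrics are
averaged within repeats, pooled held-out scores build one ROC per model, and
AUC is computed by trapezoid (it equals the rank statistic, which the tests
check). The paper-style RF protocol (10 refits, metrics from out-of-bag
votes) is additionally available as `rf_refit_report`. Undefined metric
ratios (zero denominators) are reported as NaN, never as 0; both the
conventional FPR (FP/(FP+TN)) and the alternative FP/(FP+FN) variant are
reported side by side under distinct names.

Sensitivity analysis is 1-D: each feature is varied over a 7-point grid
spanning its observed range with the others held at their training means;
importance is the variance (population, ddof = 0) of the model's OP
probability over the grid.

The cross-dataset harness scores a fitted model on 50 bootstrap samples
(70% of the table, drawn with replacement) from each of two tables and
compares the accuracy vectors with Welch's t-test. When both vectors are
constant (a separable table scored perfectly) the t statistic is undefined;
p is then defined as 1.0 if the means agree and 0.0 otherwise — identical
samples carry no evidence against the null.

## Map assembly and control signals

Junctions labelled OP (confirmed) or voted OP are chained into maximal
operon calls; assembly is order-independent and each gene appears in at most
one call. Predicted promoters/terminators flag a junction on ≥ 1 bp overlap
with its IGR; stranded signals must match the call's strand. Flagged
junctions stay in the map and are reported — signals add confidence, they do
not filter. Flanking regions of a call are not screened (the call may be
part of a larger unit).

## Synthetic data generator

Defaults (the shipped study conditions): 300 transcription units with sizes
from a geometric(0.5) truncated to [1, 8] on both strands; gene lengths
uniform 300–900 nt (codon multiples); intra-operon IGRs ~ N(20, 15) floored
at −20 (overlaps allowed); between-TU IGRs ~ N(150, 60) floored at 60;
per-TU log₂ expression level ~ N(6, 2) giving a plateau mean depth of
2^level reads/base over a 0.2 background; 15% of TUs silent per condition;
10% internal-start usage; Poisson depth noise (a dispersion knob switches to
negative binomial); read length 50; 10% of reference operons corrupted by
random splits or merges; per-operon codon preferences drawn from a
Dirichlet(0.5) per synonymous family and shared by all genes of the TU.
Condition dependence is simulated by re-drawing the silent set, levels,
UTRs and internal starts per condition from the same genome.

Three structural choices deserve note:

* **Between-TU floor of 60 nt.** The detector's spatial resolution is half
  its window: a boundary with fewer than 50 nt of clear background on one
  side has its window contaminated by the neighbouring plateau, making
  |r| = 1 unattainable and shifting the best window off the boundary. The
  floor keeps every between-TU boundary above that resolution limit, so the
  ideal-step regime (noise off) recovers each boundary exactly. UTR lengths
  (uniform 10–40 nt per end) are likewise clamped so at least ~60 nt of
  background separates adjacent plateaus.
* **Internal starts need intergenic space.** Internal transcription starts
  are placed only at intra-operon junctions with ≥ 2 nt of IGR, and the
  internal 5′UTR stays inside that IGR. At an overlapping junction an
  internal transcript would necessarily cover part of the upstream
  (untranscribed) gene, making the ground-truth pair label ill-posed.
* **Condition-dependence exactness** is checked in the noise-free regime
  *with an uncorrupted reference*: reference corruption creates unlabelled
  pairs whose voted class depends on per-condition trained classifiers,
  which is stochastic by design and not an exact set operation.

What the generator does **not** emulate: GC/mappability bias, non-uniform
read distribution along transcripts, transcription-length bias, antisense
transcription, overlapping TUs on opposite strands, rRNA contamination, and
multi-replicon genomes. Passing tests therefore demonstrate correctness of
the algorithmic chain under the stated model, not performance on real
libraries, whose discriminative signal depends on sequencing depth, strand
specificity and coverage uniformity.

## Problem sizes and determinism

The shipped defaults produce ≈ 430 kb genomes with ≈ 570 genes and ≈ 380
labelled pairs — large enough that the feature-table regime (including the
~60/40 OP/NOP imbalance) matches the method's intended operating point while
keeping the full test suite and the acceptance script in the minutes range.
All randomness flows from explicit seeds through `numpy.random.SeedSequence`
(splits, folds and bootstraps record derived seeds); pipelines rerun
byte-identically, and computation is single-threaded.

## File formats

GFF3 for annotation (CDS/gene features with unique `ID`s), FASTA for CDS
sequences keyed by gene id, samtools pileup or 2-/3-column position/depth
TSV for coverage, BED for predicted signals (name column `kind:source`,
e.g. `terminator:tt`), and a minimal two-column projection of a DOOR-style
flat file for the reference map: `operon_id TAB comma-separated gene ids`.
To convert a real DOOR flat file, group its rows by operon id and join the
gene/locus-tag column — only those two columns are consumed; gene ids must
match the annotation's `ID`/`locus_tag` attributes.

## Known limitations

Single replicon only; genes silent under the measured condition cannot be
assigned (their operons are simply absent from that condition's map, which
is the intended semantics); detection cannot resolve boundaries closer than
half a window; very weakly expressed TUs (plateau ≲ 3–4 reads/base) escape
detection; and the voting stage needs enough confirmed OPs *and* NOPs
(≥ 5 each by default) to train — on profiles without that seed set the map
contains confirmed junctions only.
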