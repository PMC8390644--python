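# Methods

This note documents the models and procedures `statepipe` implements, the
assumptions behind its synthetic-data generators, the numerical choices that
were genuinely open, and known limitations. Every number quoted here is
computed by the test suite or by `scripts/acceptance.py`.

## AP-MS interactor calling

**Model.** A bait pull-down and a matched control IP are repeated across a
roster of k experiments (default 4). For a protein with bait spectral counts
x and control counts y in one experiment, the enrichment statistic is
`s = (x / (y + c)) · x` with control pseudocount `c = 1` (configurable). The
squared dependence on x deliberately rewards high absolute spectral counts,
which matters on sensitive instruments where ratio alone saturates; the
pseudocount keeps the ratio defined at y = 0.

**Filter cascade (in order).** (1) identification quality: score strictly
greater than 10 and peptides strictly greater than 2, named common
contaminants (trypsin, keratins, actin, tubulins) removed; duplicate records
per protein/experiment collapsed to the max-bait-count record (a
sum-across-slices option exists); (2) replication: detected in at least 3 of
the 4 roster experiments; (3) contaminant frequency: strictly above 20% in a
CRAPome-style frequency table removes the protein, absent proteins count as
frequency 0. Filters run before any p-value is computed so the empirical
null is built only from plausible candidates.

**Scoring.** Within each experiment the background for the empirical p-value
is the statistic of every surviving protein detected in that experiment, the
query included, so `p = #{s' ≥ s} / N ∈ [1/N, 1]`. A protein that passed the
3-of-4 gate but is undetected in one experiment contributes `p = 1` for that
experiment — the conservative choice; the combination is therefore always
over the full roster. The combined cumulative probability

CCP(p₁..p_k) = z · Σ_{j=0}^{k−1} (−ln z)^j / j!, z = Π p_e

is the exact CDF of a product of k independent Uniform(0,1) variables,
equivalently the regularized upper incomplete gamma function Q(k, −ln z);
tests cross-check both identities and Monte-Carlo estimates at 10⁶ draws.
Because the empirical p-values are discrete and therefore stochastically no
smaller than uniform, the CCP is slightly conservative. Benjamini–Hochberg
(step-up; Benjamini–Yekutieli available) across proteins and `q ≤ 0.1` give
the calls.

**Calibration (computed by the acceptance script).** Under a null generator
(enrichment fold 1, 2,000 proteins, 20 seeds) the per-experiment empirical
p-values are uniform (KS and χ² goodness-of-fit p > 0.01) and the caller
makes essentially zero calls. With 30 planted 10-fold-enriched preys and 10%
per-experiment dropout, mean sensitivity over 50 seeds is ≈ 0.88 with
realized FDR < 0.01; the misses are dominated by the 3-of-4 detection gate,
not by scoring.

## Interval kernel

Coordinates are 0-based half-open throughout (BED convention). Merging
coalesces overlapping and book-ended intervals, matching default
merge-tool behaviour. Reciprocal overlap at fraction f defaults to
*either-interval* semantics (the overlap covers ≥ f of a **or** ≥ f of b),
matching `-f 0.25 -F 0.25 -e` flags; an AND mode is a switch, since prose
descriptions of "mutual overlap" and those flags disagree. Shared-peak
counting reports the number of merged regions in the union of qualifying
intervals from both sets — a single shared count that can be quoted against
either set's total — alongside per-set qualifying counts, because the two
readings coincide only when qualifying intervals pair one-to-one. Percentages
round half-up to one decimal. Target genes are assigned by nearest TSS to
the peak midpoint `floor((start+end)/2)`, strictly closer than 20 kb, ties
broken to the lexicographically smaller gene id. Overlap enrichment is a
one-sided (greater) Fisher exact test via `scipy.stats.fisher_exact`. All
operations are tested against O(n²)/exhaustive oracles on random instances.

One worked-example note: the shared-fraction arithmetic reproduces the
published 53.0 / 58.0 / 57.9 / 88.8 / 26.3 / 27.8 / 99.9 percentages and the
69,007 peak union exactly from the printed integer counts, but 15,839/21,359
equals 74.156%, which is **74.2** under half-up rounding; the published 74.1
for that single pair is consistent only with truncation, so this package
reports 74.2.

## Occupancy matrix and chromatin-state clustering

The occupancy matrix over merged peaks carries a binary layer (reciprocal-
overlap flags against each factor/state track) and an optional intensity
layer (mean per-base signal). For clustering, intensity tracks are each
scaled by their 95th percentile and clipped to [0, 1], bounding outlier
peaks; the binary layer needs no scaling. Whether binary flags or intensities
feed the clustering is a caller choice — both recover planted classes in
tests.

k-means is implemented directly (Lloyd, best of `n_restarts` seedings,
squared-Euclidean objective) rather than delegated, because the contract here
pins semantics a generic implementation does not expose: the within-run
objective is asserted non-increasing at every iteration, an empty cluster is
re-seeded from the point currently farthest from its centroid, and the
returned model is the restart with minimal within-cluster sum of squares.
`sklearn.cluster.KMeans` is the independent cross-check in tests (identical
inertia and partition on separated blobs). Defaults follow the published
protocol (k = 10, 1,000 iterations, 1,000 restarts); the CLI's `fast` profile
uses 50 restarts, which on landscapes of this size reaches the same optimum.

Cluster annotation is a pure function of the (normalized) centroids with
threshold τ = 0.5: per state, *enhancer* = OCT4 ≥ τ ∧ H3K27ac ≥ τ ∧
H3K4me3 < τ ∧ H3K27me3 < τ; *active promoter* = the same with H3K4me3 ≥ τ;
*bivalent* = H3K4me3 ≥ τ ∧ H3K27me3 ≥ τ. A pattern holding in one state but
not the other gives the state-specific label; in both, the shared label.
Evaluation order is bivalent (both states) → enhancers → promoters → other,
so a centroid that is, say, enhancer-like in the naive state and
promoter-like in the primed state is reported by its naive enhancer
character. Labels outside the recognized patterns (including primed-only
active promoters) fall to `other`. On the default planted landscape (3,000
peaks, six classes, signal/noise 10) k-means at k = 6 plus annotation
recovers > 99% of peaks and every class proportion within 0.001.

## Differential expression

Matrices are RPKM (single-end) or FPKM (paired-end); the pseudocount — 0.1
for RPKM, 1 for FPKM — is added exactly once (the wrapper tracks it) to damp
fold changes of low-expression genes. The DEG rule is an unpaired two-sided
pooled-variance t-test (Welch by flag) with fold change = mean_B/mean_A on
the pseudocounted scale: significant iff p < 0.05 (strict) and fold change
> 2 or < 1/2 (strict). Zero variance in both groups with equal means gives
p = 1 by convention. The low-expression filter drops genes with mean over
samples of log2(FPKM+1) strictly below 1, applied to raw values before the
pseudocount. Group comparisons of expression distributions use the two-sided
Mann–Whitney test, exact for ≤ 8 untied observations per group, normal
approximation with tie correction otherwise.

## Differential accessibility

The caller is a deliberately transparent, self-contained procedure —
counts-per-million, log2(x+1), per-peak unpaired two-sided t, BH across
peaks, strict q < 0.05 — defined here so the stage is fully specified and
testable; it is not a re-implementation of any particular differential-
binding package. Effective library sizes default to median-of-ratios size
factors (rescaled to the column-sum scale) rather than raw column sums:
when a knockout removes a sizable slice of the signal in one arm, raw column
sums shrink there and CPM inflates every unchanged peak, which both biases
null peaks upward and dilutes the planted effect. Median-of-ratios assumes
the *majority* of peaks are unchanged; with ≳ 30–40% of peaks perturbed in
one direction it too overcorrects (visible as spurious "up" calls in a
deliberately extreme fixture), which is the standard, documented failure
mode of composition-robust normalization.

Per-cluster enrichment of significant peaks compares the observed count in
each annotated class against the size-proportional expectation
`expected_c = n_significant × proportion_c` (reported unrounded) with a
one-sided Fisher exact test on the corresponding 2×2 table.

**Power, honestly stated.** At the generator's study conditions — negative-
binomial counts with dispersion α = 0.1, baseline mean 400 with log-normal
spread (sd 0.6), 8-fold depletion, 3 replicates per arm, 1,000 planted of
10,000 peaks — the unmoderated per-peak t (4 degrees of freedom, residual
sd ≈ √0.1/ln 2 ≈ 0.46 in log2 units) recovers ≈ 0.76 of planted losses at
FDR < 0.05, with realized FDR ≈ 0.05. A moderated-dispersion engine of the
kind real studies use would clear 0.8 under the same conditions; this
package keeps the transparent t-based caller and reports its measured
power rather than tuning the generator to flatter it.

## Synthetic-data generators

All generators are pure functions of their config (seed included): same
config, byte-identical outputs. Truth labels accompany every dataset.

* **AP-MS** (`simulate_apms` / `simulate_crapome`): spectral counts are
  negative-binomial (gamma-Poisson, dispersion 0.2) with background mean 10
  in both bait and control for non-interactors; true preys multiply the bait
  mean by the enrichment fold (fold 1 = the null configuration) and drop out
  of single experiments with probability 0.1. About 5% of records are
  sampled to fail the identification gate. Contaminant frequencies sit on
  the k/runs grid; sticky contaminants (10% of background) draw from
  (0.2, 1], everything else from [0, 0.2], so the frequency filter's truth
  is unambiguous.
* **Peak landscape** (`simulate_peak_landscape`): three synthetic
  chromosomes (60/40/25 Mb), disjoint peaks with log-normal widths around
  500 bp, six planted classes whose on/off track patterns match the
  annotation rules exactly; "on" tracks draw mean intensity 10, "off" tracks
  1 (signal/noise 10), with 25% CV log-normal noise; per-track peak BEDs are
  jittered ±50 bp. 80% of promoter-class peaks get a TSS within 15 kb of
  their midpoint.
* **Expression** (`simulate_expression`): per-gene baselines are log-normal
  around FPKM 20; replicate noise is *Gaussian* with CV = dispersion
  (default 0.1), truncated at 0 (negligible at these means), so the t-test's
  null distribution is exact and null calibration tests the caller rather
  than a noise-model mismatch. Planted DEGs shift the comparison mean by
  ±effect_log2fc (default 3).
* **ATAC counts** (`simulate_atac_counts`): negative-binomial with
  dispersion 0.1, baseline means log-normal around 400 (sd 0.6); planted
  DARs scale the knockout-arm mean by 2^±effect. Passing the landscape's
  class labels plants the loss in exactly the chosen classes, emulating a
  knockout that collapses specific enhancer classes.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: correlated replicates and batch effects; peak-width /
signal coupling; fragment-level ATAC structure (counts are drawn directly);
mark intensities that vary continuously across classes rather than switching
between two means; protein-complex structure in AP-MS (preys are
independent); and real contaminant-frequency distributions. Recovery rates
measured here are therefore upper bounds on what identical settings would
achieve on real data.

## Problem sizes and determinism

Test and acceptance runs use: 2,000 proteins × 4 experiments × (20 null + 50
planted) seeds for interactor calibration; 10⁶ Monte-Carlo draws per k for
the CCP check; 1,000 random vectors (length ≤ 50) for the BH oracle; 100
random instances of ≤ 500 intervals for the interval kernel; a 3,000-peak
six-class landscape with 25 k-means restarts; 5,000 genes and 10,000 peaks
(5 seeds) for differential calibration; and a 1,010-peak end-to-end knockout
study. The full suite runs in about a minute; `scripts/acceptance.py` in
about half a minute. All randomness flows from explicit seed fields — no
global RNG state anywhere.
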