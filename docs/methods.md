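# Methods

This note records the statistical model behind each stage of `aluscancnv`,
the defaults and why they were chosen, the numerical decisions that were
genuinely open, and what the synthetic-data tests do and do not establish
about real capture data.

## Depth model and windowing

The unit of analysis is a fixed-size genomic window (0-based, half-open
coordinates).  Depth is the count of read 5′ start positions per window —
a count statistic, which is what the Poisson model describes; per-base
coverage would not be Poisson at the window level.  Windows tile each
chromosome contiguously; the last window per chromosome is truncated.
Sex chromosomes and unplaced contigs are excluded by default.

Capture by inter-Alu PCR leaves most windows with zero depth, so the
95%-quantile winsorization rule is applied to the *positive*-depth
distribution only (linear interpolation between order statistics), at the
base 5 kb window size, before any merging.  Zero-inflated profiles would
otherwise place the 95% quantile at or near zero and destroy the signal.
Winsorization is idempotent.  Merging to 100/300/500 kb sums constituent
depths exactly (total reads conserved) and carries a length-weighted GC.

GC fraction counts G+C over unambiguous bases only; windows with no
unambiguous base carry an undefined GC and never enter GC-stratified
statistics.  GC stratification everywhere uses 20 groups of 5% width,
`floor(gc/0.05)` with gc = 1.0 clamped into group 19.

## Localized calling (Geary–Hinkley transformation)

Window depth R ~ Poisson(λ) ≈ N(λ, λ).  For the raw per-window ratio
z = R_t/R_c of two such variables, the Geary–Hinkley transformation

    t = (λ_c z − λ_t) / sqrt(λ_c z² + λ_t)

is approximately standard normal, with λ_t, λ_c the mean depths over the
analysis set — the windows with positive depth in both samples (zero-depth
windows carry no ratio information).  Two properties matter in practice:

* **Self-centering.**  The statistic is centered at z = λ_t/λ_c, so it
  remains calibrated when the control side is a pooled reference template
  whose depths and totals are many times the test sample's.  Applying the
  transformation to the total-read-adjusted ratio instead, with the
  template's raw mean depth, shifts t by ~λ_t(k−1)/√(λ_t(k+1)) for a
  k-fold pooled template and calls essentially every window; the raw-ratio
  form is therefore the operational definition used here.  The adjusted
  ratio r = z·N_c/N_t expresses the same comparison on the dosage scale
  and decides the direction: gain when p < α and r > 1, loss when p < α
  and r < 1; r = 1 is always neutral with p := 1.  With matched totals
  (the paired design) z and r coincide and the two forms are identical.
* **Depth regime.**  The normal approximation needs adequate depth.  The
  package's own null calibration places the empirical t at |mean| < 0.02
  and |sd − 1| < 0.02 for λ = 100; by λ ≈ 50 calibration is still
  acceptable, and below that the caller should not be trusted.  This λ ≥ 50
  guidance comes from our simulations, not from an external derivation.

The two-sided p-value is p = 2(1 − Φ(t)) for r > 1 and p = 2Φ(t) for
r < 1, Φ the standard normal CDF (scipy, accurate to ≥1e-12), clipped to
[0, 1] in the sliver where the sign of t and the side of r disagree (the
library-size ratio and the analyzed-window mean-depth ratio can differ
slightly).  α defaults to 0.05 with no multiple-testing correction at this
stage.  Recommended window sizes: 500 kb for localized calling, 5 kb for
segmentation input; both are parameters.

GC mode replaces λ_t, λ_c by per-GC-group means computed over the analysis
set of the comparison at hand.  Groups with fewer than 30 analysis windows
(configurable) fall back to the global λ's with a warning — means over
near-empty groups are too unstable to stratify on.

**Limitation.**  A single λ_c assumes the control's windows share one
rate.  Pooling reference samples whose capture masks differ makes the
pooled depth mixture-distributed (a window is covered by a random number
of references), which mis-calibrates the statistic.  The intended regime —
one primer set across all samples, hence concordant capture masks —
avoids this; templates should be built from libraries prepared like the
test samples.

## Recurrent CNVs (Poisson-binomial tail)

Per-window gain (or loss; the two are analyzed separately) indicators over
a cohort form a binary m × n matrix, restricted to windows analyzable in
every sample.  Treating alterations as independent across samples with
per-sample rates p_j estimated by column means, the count of samples
sharing a CNV at a window is Poisson-binomial.  The pmf is computed
exactly by iterative convolution — O(n²), numerically stable, exact to
≤1e-12 against exhaustive enumeration for n ≤ 12 and normalized to 1e-9 at
n = 1000.  A window is recurrent when its count reaches
k* = min{k : P(K ≥ k) < 0.01}.  An optional Bonferroni flag tightens the
level to 0.01/m; it is off by default.  Because the cutoff is discrete,
the realized false-flag rate on null matrices sits well below the nominal
level (conservative).

## Extended CNVs (GC correction, Z scores, CBS)

Per sample, depths over the analysis set are GC-corrected:
D_corr = D_global · D_raw / D_GC with D_global the median depth of
analyzed windows and D_GC the group median (medians, being the convention
for this correction and robust to the winsorized tail).  Groups with zero
median pass through uncorrected.  The corrected ratio
r = D_t-corr / D_c-corr is standardized as Z = (ln r − mean)/sd over all
analyzed windows of the test sample, with the sample (n−1) standard
deviation — the conventional estimator; the choice is invisible beyond
~4 significant digits at realistic window counts.

Circular binary segmentation then partitions each chromosome: over all
arcs (i, j] of the circularized window sequence with both arc and
complement at least `min_width` = 2 windows, the statistic

    |mean(arc) − mean(complement)| / (s · sqrt(1/l + 1/(n−l)))

is maximized (s the segment's standard deviation, held fixed), and the
split is accepted when its permutation p-value is below α_seg = 0.01,
recursing until nothing splits.  The permutation reference uses up to
n_perm = 10,000 within-segment permutations with sequential early
stopping: a split is rejected as soon as the exceedance count makes
p ≥ α_seg inevitable at the configured budget (exact), and accepted early
once at least 500 permutations have produced zero exceedances (the
binomial upper bound on p is then far below α_seg).  Early stopping
changes runtimes, not decisions at the nominal level, except through that
bound.  Segmentation is deterministic for a fixed seed, and the
first-split search agrees exactly with exhaustive enumeration on
chromosomes of ≤ 60 windows (tested).

Segments are classified by mean Z against an inclusive threshold of 0.2:
gain at Z ≥ 0.2, loss at Z ≤ −0.2.  The Pearson correlation between test
and control depths over common windows is computed as the QC prerequisite;
segmentation results on poorly correlated pairs should be discarded.

## CNV-feature selection and classification

CFS merit of a k-feature subset is k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) with
feature–class and feature–feature correlations measured by symmetrical
uncertainty SU = 2·I(X;Y)/(H(X)+H(Y)) on the binary variables.  Search is
best-first over subsets (priority queue, five-stale-expansion stop,
deterministic low-index tie-break) followed by the locally-predictive
post-pass of the CfsSubsetEval convention: remaining features are visited
in decreasing class-correlation order and added when their class
correlation exceeds their strongest correlation with any selected feature.
Two behaviours of CFS are worth knowing: a single perfectly separating
feature yields a one-feature selection (redundant copies are penalized by
design), and on pure noise the merit grows like c·√k for weak
near-independent features, so a small percentage of spurious features is
always admitted.

Classification is Bernoulli Naïve Bayes with Laplace smoothing, evaluated
by repeated stratified two-fold cross-validation (1,000 iterations by
default).  Each iteration scores every sample once from the model trained
on the opposite fold; AUC is computed per iteration from the pooled
posteriors and averaged, and the F-score 2TP/(2TP+FP+FN) comes from
confusion counts pooled over all iterations at a 0.5 posterior threshold.
Per-iteration-averaged AUC was chosen over globally pooled AUC to keep
iterations exchangeable; with 1,000 iterations the two agree closely.

Clustering is agglomerative with Euclidean distances and Ward's method in
its unsquared "ward.D" form (realized by the squared-form algorithm on
sqrt-distances with squared merge heights; verified against R's hclust).
Node support is the plain proportion of feature-bootstrap trees containing
the node's leaf set — not multiscale "approximately unbiased"
probabilities, which are out of scope; plain proportions are known to be
conservative for well-separated clades.

## Synthetic data: what it emulates, and what not

The generator draws window GC from a clipped normal(0.41, 0.07), covers a
configurable fraction of windows (default 0.3, mimicking inter-Alu
sparsity), draws covered depths Poisson with base rate 100, applies a
smooth unimodal capture-efficiency multiplier 0.5 + exp(−((gc−0.45)/0.10)²)
ranging over [0.5, 1.5], and injects CNVs as multiplicative fold changes
on window runs.  The bias width 0.10 makes capture efficiency vary
materially across the interquartile GC range, emulating the regime where
GC normalization visibly rescues calibration (as when test and reference
libraries are amplified with mismatched primer sets).  Everything is
deterministic given a seed.

Not emulated: read-level artifacts (mapping ambiguity, duplicates),
overdispersion beyond Poisson, correlated capture failure along the
genome, subclonal mixtures, and real GC-bias shapes.  Passing tests
therefore establish the correctness and calibration of the statistics
under the stated model, not performance on any particular real library.
Problem sizes used by the test suite — 100,000 windows for null
calibration, 20,000 × 38 for recurrence, 1,000-window chromosomes × 100
seeded runs for CBS recovery, 40 × 2,010 for the classifier — were chosen
as the smallest scales at which the binomial error bars make the
calibration statements sharp.

## Degenerate inputs

Empty window sets, all-zero profiles, disjoint coverage supports,
constant-depth vectors (zero variance), single-sample recurrence matrices,
single-class label files and zero-median GC groups are all rejected with
specific errors or handled by documented fallbacks rather than producing
numbers silently; see the per-function docstrings.
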