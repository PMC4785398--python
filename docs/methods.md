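# Methods

This note documents the models, algorithms, parameter choices and
simulation scales behind `mosquito_microgeo`, and what the synthetic
benchmarks do and do not demonstrate about real data.

## Synthetic community model

The generator emulates whole-body 16S profiles of mosquitoes sampled in
a small number of villages.

**Abundance structure.** Each class (village) k has an expected
relative-abundance profile over all OTUs. Background OTU baseline
weights are i.i.d. log-normal(0, σ²) with σ = 2.0 by default — a heavy
right tail, so a handful of background OTUs dominate and most are rare,
as in real amplicon tables. Each class additionally owns
`n_signature_otus_per_class` signature OTUs (default 4) whose weight is
multiplied by `signature_fold_change` (default 5) in the home class.
Signature baseline weights are log-normal with log-mean 3.4 (≈ a few
percent relative abundance each): the village-marker genera in real
mosquito data (*Wolbachia* reaching 36–47% of a sample, *Massilia*,
*Acinetobacter*) are dominant community members, so rare markers would
not emulate the phenomenon. Baselines are shared position-wise across
classes, which makes every class profile's normaliser identical, so the
home/away ratio of a signature OTU's expected *relative* abundance
equals the fold change exactly — the property the generator is tested
against.

**Counts.** Per-sample depth is log-normal; the default parameters
(μ = 9.5297, σ = 0.6758) are the method-of-moments fit to a natural-scale
mean of 17,300 and SD of 13,162 reads, the depth spread the pipeline is
designed for (including samples below the 7,500-read filter). Given the
depth, counts are a single multinomial draw from the class profile.
Multinomial sampling is the simplest model satisfying the pipeline's
tests; real amplicon data are overdispersed relative to it, so an
optional Dirichlet-multinomial mode (`overdispersion=c`, concentration
c·profile) is available. Under the multinomial default, within-village
community variation is pure counting noise, which makes classification
*easier* than on real data — the strong-signal accuracy benchmarks are
power analogues, not accuracy claims about field samples.

**Migrants.** A migrant is defined at the expected-profile level: its
profile is `w·source + (1−w)·home`. This matches the interpretation of a
migrant as an individual whose exposure history spans two villages; it
does not model read-level mixtures or recent-arrival kinetics.

**Defaults** (29 samples in classes 10/10/9, three villages) mirror the
post-filtering sample count the pipeline is dimensioned for; the
per-village split is a choice, not a reported value.

## Preprocessing

Samples with fewer than `min_reads` (default 7,500) total reads are
removed; a sample exactly at the threshold is kept. Remaining samples
are rarefied — subsampled *without replacement* (multivariate
hypergeometric, `numpy.random.Generator.multivariate_hypergeometric`) —
to a common depth, by default the minimum sample depth. Without
replacement is the ecological convention and gives exactly
hypergeometric per-OTU moments, which the tests exploit. Analytic
rarefaction curves use `E[S(d)] = Σᵢ (1 − C(N−Nᵢ,d)/C(N,d))` evaluated
via log-gamma to avoid overflow at realistic depths.

Rarefaction precedes both ordination and classification. The analysis
keeps this ordering configurable only in the sense that the library
functions accept any table; the pipeline applies filter → rarefy first.

## Community analyses

**Horn dissimilarity.** Implemented as the abundance-based
Morisita–Horn index (the formula behind the "horn" method of the
standard R community-ecology distance function, against which the
implementation is cross-checked in the tests):
`d = 1 − 2Σxᵢyᵢ/[(Σxᵢ²/X² + Σyᵢ²/Y²)XY]`. This is *not* Horn's 1966
information-theoretic overlap. It is symmetric, in [0,1], zero iff the
relative profiles coincide, and invariant to per-sample depth rescaling.

**NMDS.** Kruskal stress-1 minimised by alternating isotonic regression
(monotone transform of the input dissimilarities onto configuration
distances, ties averaged) with Guttman-transform configuration updates.
One deterministic Torgerson (classical scaling) start plus `n_starts`
(default 8) random starts; the best configuration is returned, so its
stress never exceeds the metric start's. Convergence is a stress
decrease below `tol` (1e-7) within `max_iter` (300) iterations;
non-convergence sets a flag rather than raising. No abundance
autotransform is applied before the distance computation.

**PERMANOVA.** One-factor pseudo-F from squared-distance partitioning
(`SS_total = Σd²ᵢⱼ/n`, within-group analogue per group), significance by
label shuffling with the unbiased `(1+hits)/(1+n_perm)` convention.
Default 9,999 permutations; up to 10⁶ via configuration. Verified
against both an exhaustive enumeration at n = 6 and two independent
implementations (scikit-bio, R vegan).

## Repeated double cross-validation (rdCV)

The classifier is a random forest evaluated inside a nested CV scheme:

* Outer loop: `n_outer` = 6 stratified folds (~4–5 held-out samples at
  n = 29). Each fold's samples are predicted by a forest that never saw
  them.
* Inner loop: on each outer-training set, `n_inner` = 5 stratified folds
  tune the number of OTUs by backward elimination. At each step every
  inner-segment forest is fit on the active OTUs; OTUs are ranked by
  importance within each model (descending, ties averaged) and the
  `ceil(0.10·|active|)` with the worst average rank are removed (never
  below `min_otus` = 2; ties at the cut broken by stable OTU order). The
  OTU set minimising total inner-validation misclassifications is
  selected, ties toward fewer OTUs (parsimony).
* One forest per outer fold is refit on the outer-training set
  restricted to the selected OTUs and yields class probabilities for the
  held-out fold.
* The double loop is repeated `n_rep` times (full-scale default 200)
  with fresh folds; repetition r draws all its randomness from a child
  stream seeded by (seed, r). The consensus class is the argmax of the
  repetition-mean probability vector (lexicographic class order breaks
  exact ties).

Features are per-sample relative abundances. Fold counts are this
package's choice (the procedure's description does not fix them);
stratification is on by default because unstratified folds at n ≈ 29
with three classes frequently lose a class from a training set.

**Importance.** The elimination ranking and the reported per-OTU average
rank use the forest's impurity (Gini) importance by default. Out-of-bag
permutation importance is available (`importance="permutation"`) but
costs O(n_features) prediction passes per forest, which is prohibitive
inside the elimination loop at desk scale; for the strong, sparse
signals the ranking step must resolve, the two measures order OTUs the
same way in practice. OTUs eliminated before an outer model was fit are
assigned the average of the remaining rank positions, so every OTU has a
rank in every model. Genus-level summaries take the best OTU rank per
genus.

**Estimator interface.** `RdcvClassifier` wraps the procedure in a
scikit-learn estimator: `fit` runs the full scheme and exposes the
probability population (`prob_`), consensus (`consensus_class_`,
`n_misclassified_`) and importance ranking; prediction of *new* samples
uses a deployment forest refit on all training data restricted to the
top-k OTUs (k = median selected set size across outer models). The
deployment forest is a convenience beyond the core procedure, whose
purpose is held-out characterisation of the training samples.

## Permutation validity test

The H0 population collects misclassification counts from models fitted
after permuting the labels uniformly without replacement. The observed
count's p-value is the lower tail of a Student-t with df = n_models − 1,
location/scale fitted by the population's sample moments — the minimal
reading of "a t-distributed H0 population"; skewness and excess kurtosis
are reported as shape diagnostics in place of a histogram inspection.

The closed-form no-information expectation is
`E[miss] = n − Σₖnₖ²/n` (= 19.31 for 10/10/9; (1−1/K)n for balanced
classes). It assumes predictions are drawn independently of the permuted
labels with the data's class frequencies. A nested-CV null can deviate
slightly from it: the training set always lacks the held-out sample, so
its class is under-represented by one, and whenever the held-out
prediction effectively copies a training sample's label — with very
small forests (which memorise), or on strongly clustered data (where
prediction follows cluster membership and so draws a label from the
sample's own cluster-mates) — the match probability drops to
Σₖnₖ(nₖ−1)/(n(n−1)) (E[miss] = 20.07 at 10/10/9). Simulation confirms both regimes: 10-tree outer forests give a
null mean near 20.1, while outer forests at the observed model's size
(100 trees) give ≈ 19.4. Null models therefore keep the observed model's
outer forest size and reduce only the repetition count (`null_reps`,
default 10; 1 in the acceptance runs) — the knob the procedure's design
explicitly treats as reducible — plus desk-scale inner settings noted
below.

## Problem sizes used in the shipped benchmarks

Chosen as the package's own desk-scale defaults; all are configurable.

* Estimated-H0-mean benchmark: 29 samples (10/10/9), a 12-OTU
  no-signal table (the null level depends only on label permutation and
  class sizes), 200 null models, each 1 repetition of the double loop
  with 6 outer / 2 inner folds, 100-tree outer and 10-tree inner
  forests.
* Classification-power benchmark: generator defaults (4 signature
  OTUs/village at 5-fold enrichment, 200 background OTUs), rarefied to
  the minimum depth, rdCV with 5 repetitions, 100-tree outer / 20-tree
  inner forests, averaged over 3 datasets (the full-scale analogue is
  200 repetitions; repetitions only stabilise the consensus, they do not
  change the signal).
* Test-suite statistical checks run smaller still (2–3 outer folds,
  5–30-tree forests, 8–200 null models) and assert distributional
  properties (calibration, convergence to closed forms) rather than
  point reproduction.

## Numerical and degenerate-input conventions

Counts are validated as non-negative integers; duplicate sample/OTU ids
are rejected. Zero-depth samples are refused by distance and
relative-abundance computations (named in the error). Zero-variance
features yield NaN co-occurrence entries rather than errors. A
degenerate H0 population (sd = 0) refuses to produce a p-value.
Isotonic ties are averaged; argmax ties resolve to the lexicographically
first class; elimination ties at the cut preserve stable OTU order. All
stages are deterministic given their seed; the pipeline manifest records
every seed and input hash.

## Known limitations

* Multinomial counts understate real within-village heterogeneity;
  enable `overdispersion` for harder, more realistic benchmarks.
* The generator does not simulate sequences, chimeras or taxonomy
  errors; taxonomy strings are labels, not biology.
* NMDS applies no Wisconsin/sqrt autotransform, so configurations are
  not directly comparable to tools that autotransform by default.
* The t-based validity p-value inherits the t-shape assumption; inspect
  the reported skewness/kurtosis before trusting extreme p-values.
* With ~29 samples, PERMANOVA and the rdCV null have limited resolution;
  p-values below 1/(n_perm+1) are not attainable by construction.
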