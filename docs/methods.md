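# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `avalanchestates`. It is the package's own account of its
science; every empirical statement here is one that the test suite or
`scripts/acceptance.py` computes.

## Avalanche extraction

Each region's signal is standardised over the full recording (population SD,
divide by T; at T ≈ 9×10⁴ samples the difference from the sample SD is
immaterial, but the convention is fixed so results are exactly
reproducible). Binarisation marks samples with |z| strictly greater than the
threshold (default 3 SD). Two sign conventions exist in the literature;
absolute value is the default, positive-only excursions are available via
`mode="positive"`. A value exactly at the threshold is inactive — a
measure-zero event, but determinism requires a rule.

An avalanche is a maximal run of samples with at least one active region;
runs touching either end of the recording count. Intervals are 0-based and
half-open throughout. No minimum size or duration filter is applied. The
avalanche *pattern* is the OR over the interval's columns: which regions
were recruited at any moment, internal timing discarded. Unique patterns
(exact binary equality, pooled across subjects by default, per-subject scope
available) feed the embedding; labels found for unique patterns are
propagated back to all occurrences for topographies and transitions.

## Diffusion embedding

The embedding follows the potential-of-heat-diffusion construction:

1. PCA to `n_pca` = 5 components (full SVD; rank-deficient inputs return
   rank-many components with a warning).
2. Cosine distances between pattern scores — natural for binary recruitment
   vectors, where co-recruitment overlap matters and vector length encodes
   avalanche size.
3. α-decay kernel with adaptive bandwidth: ε_k(i) is the distance from i to
   its k-th nearest neighbour (self excluded; distance ties do not change
   the bandwidth value). Defaults k = 5, α = 1. Directed kernels are
   symmetrised by averaging; α ≥ 1 is enforced. The kernel diagnostic for
   choosing α (kNN-distance curves) is exposed as data, not an optimiser.
4. Markov (row) normalisation into a diffusion operator P.
5. Diffusion time t: the knee (maximum distance to chord) of the von Neumann
   entropy of P^t over t ∈ [1, 100]. The spectrum is obtained from the
   symmetric conjugate of P, recovered via its stationary distribution
   (power iteration); a flat entropy curve (e.g. P = I) falls back to t = 1
   with a warning. An explicit integer t can be supplied instead — useful
   both for speed and for sensitivity scans.
6. Potential distances ‖log P^t[i,·] − log P^t[j,·]‖₂ with probabilities
   floored at 10⁻¹² (entries of a stochastic matrix have magnitude ≤ 1, so
   the floor is also the relative scale). A variant embeds plain Euclidean
   distances between diffused rows (`potential="diffused_cosine"`), covering
   the alternative reading of "embedding the diffused distances directly".
7. Metric MDS by SMACOF, initialised from classical (Torgerson) MDS with a
   deterministic sign convention, so the embedding is reproducible without a
   random initialisation sweep.

Plain PCA coordinates are available through the same interface
(`method="pca"`) as the benchmark reduction.

## States and dynamics

k-means uses k-means++ seeding with `n_init` = 50 restarts (best WCSS),
tolerance 10⁻⁶, max 300 iterations — restarts are a stability addition over
a single random initialisation, seeded for reproducibility. k defaults to 7
and is always overridable; a selection report (elbow knee by max distance to
chord, mean silhouette, gap statistic with a uniform bounding-box reference
and the sqrt(1+1/B) SE correction) is available for any k range. Two gap
readings are reported: the argmax ("the higher the gap...") and the
first-k rule Gap(k) ≥ Gap(k+1) − SE(k+1). On clean well-separated blobs the
argmax finds the planted count; on diffusion-embedded avalanche data the gap
curve keeps creeping upward past the planted K because within-state
recruitment variability forms substructure — there the elbow/silhouette and
the gap *increment* are the informative readings (the k-selection test
checks exactly this).

Topographies are reported as counts and as fractions in [0,1] (the
"percentage of activity" of a region within a state); fractions feed the
entropy statistic and null models. Topographies are computed over all
avalanche occurrences by default (unique-only via flag).

Transition matrices count consecutive label pairs per subject; rows with no
outgoing transitions stay all-zero and are flagged. Pooling across subjects
excludes cross-subject boundary pairs by default (statistically correct);
`boundary_policy="include"` concatenates first, accepting one spurious
transition per junction, for fidelity with concatenation-based analyses.
Cross-run and cross-cohort cluster matching uses Pearson correlations
between topography rows: the summary statistic is the directional average
max correlation (greedy, many-to-one allowed, matching the "maximum
correlation for each cluster" convention); one-to-one alignment for
transition-matrix comparison uses the Hungarian algorithm on the same
correlation matrix.

## Null models and the entropy statistic

H(x) = −Σ xⱼ ln xⱼ over the M = N·K concatenated topography fractions, with
0 ln 0 = 0. The vector is deliberately *not* normalised to sum to one: H is
a structure statistic, zero exactly when every recruitment fraction is
deterministic (0 or 1), largest when fractions sit near 1/e spread over many
cells. Concatenation order is immaterial.

* **Label shuffle** (default 10 000 permutations): permutes state labels
  across patterns, preserving cluster sizes; recomputes topographies and H.
  Structured clusterings land in the *lower* tail (p_low). Per-(state,
  region) fractions get a two-sided trit map at α = 0.05. The embedding is
  not re-run — this null tests the labeling, not the geometry.
* **Sequence shuffle** (default 10 000): permutes the chronological order of
  labels within subject (or of the pooled concatenation), preserving
  occupancies; per-cell transition probabilities get two-sided empirical
  p-values (doubled smaller tail, capped at 1; one-sided available) and a
  ±1/0 mask at α = 0.05. A constant sequence is its own shuffle, so its
  self-transition cell gets p = 1.
* **Region shuffle** (default 999 permutations, because each one re-runs
  the embedding and clustering): permutes region positions independently
  within every pattern, preserving per-pattern sizes while destroying
  cross-pattern region identity, then re-runs the full pipeline. Each
  permutation's clusters are aligned to the observed clusters by Hungarian
  matching on topography correlations before the per-cell comparison
  (cluster indices are arbitrary per run; without alignment the cellwise
  null is meaningless); the map uses α = 0.2. When a shuffle leaves no more
  unique patterns than clusters, each unique pattern becomes its own
  cluster — this covers degenerate inputs (all-ones patterns shuffle to
  themselves and give p = 1) without running an under-determined embedding.

All p-values use the add-one estimator p = (1 + #extreme)/(n_perm + 1).
Permutation streams are seeded and mutually independent under one master
seed. Type-I calibration is tested: under data generated from each null,
rejection at α = 0.05 stays within 2 binomial SE of 0.05 (the sequence-based
p-values are mildly conservative because transition counts are discrete and
ties count as extreme).

**Direction of the region-shuffle test.** For the compact planted states the
generator produces, the observed entropy always sits in the *lower* tail of
the region-shuffle null: with balanced clusters and fixed per-cluster
recruitment mass, H is maximised by spreading mass uniformly over regions
(concavity of −x ln x), which is exactly what region-exchangeable reruns
produce. An upper-tail outcome requires broad, heterogeneous observed
topographies together with size-segregated null clusters — a regime real
recordings can occupy but one that directly conflicts with planting compact,
recoverable states. The package therefore reports both tails and the test
suite asserts the lower-tail extremity on synthetic data; on real data the
appropriate tail is an empirical question.

## Synthetic cohorts

The generator emulates the target regime — 90 regions, 256 Hz, 6 minutes per
subject, 18 subjects — with planted structure:

* **Topographies**: K = 7 states × 12 regions each, pairwise Jaccard overlap
  ≤ 0.2 (rejection sampling with bounded retries; zero overlap builds a
  disjoint partition, infeasible constraints raise).
* **Chain**: rows are Dirichlet(1) draws mixed with the identity,
  P = (1−b)R + bI with self-transition bias b = 0.3 by default; for b > 0
  rows are redrawn until the diagonal exceeds every off-diagonal entry by at
  least b/2, so "states tend to repeat" holds by construction.
* **Events**: Poisson count at 0.55/s, geometric durations with mean 5
  samples (memoryless transients; ~198 events and ~1.1% of samples inside
  avalanches per subject, well below the 5% sparsity ceiling typical of this
  regime), placed without overlap and with ≥ 1 silent sample between events.
  Each event's state follows the planted chain (uniform initial state). Each
  member region is recruited with probability 0.8 (≥ 1 always); one lead
  region bursts throughout the event — keeping the planted interval
  contiguous under detection — while other recruits burst per-sample with
  probability 0.7.
* **Noise**: i.i.d. standard Gaussian per region and sample, or AR(1) with
  coefficient 0.5 rescaled to unit marginal variance — the simplest
  backgrounds satisfying the z-score/threshold logic. No 1/f or forward-model
  realism is attempted.
* **Fixture mode**: truncates background noise at |z| = 2.9 and sets burst
  samples to exactly the burst amplitude (6 SD), so that after z-scoring no
  background sample crosses the threshold and every burst does — detection
  then recovers the planted intervals and patterns *exactly*, which the
  tests assert. (Purely additive bursts can dip below threshold after
  z-scoring once burst variance inflates the per-region SD; pinning the
  burst value is what makes the exactness guarantee unconditional.) Default
  mode leaves noise untruncated; with 90 regions, i.i.d. Gaussian noise
  alone crosses |z| > 3 somewhere in ≈ 21% of columns, so untruncated runs
  are dominated by single-region noise avalanches — realistic for testing
  summary statistics (the Gaussian-tail check uses it) but not for
  planted-state recovery, which uses fixture mode.
* **Seeding**: one master seed; per-subject and per-stage streams derived by
  `SeedSequence.spawn`. Identical parameters reproduce byte-identical
  cohorts.

What passing on this generator does *not* show: robustness to correlated
inter-regional background, 1/f spectra, volume-conduction leakage, state
topographies with graded (non-binary) membership, or avalanche size
distributions with heavy tails. The generator's states are cleanly separated
by design; real-data performance depends on separability the generator does
not model.

## Problem sizes and numerical choices

The study-scale validation (tests and acceptance script) uses the full
18-subject, 90-region, ~3 500-avalanche cohort for detection, embedding
(~1 800 unique patterns), clustering, transitions and the label/sequence
nulls. The region-shuffle null re-runs the embedding per permutation, so its
validations run on smaller planted cohorts (4 subjects, 30 regions,
99 permutations) and its type-I calibration on 40-pattern, 12-region
replicates with a reduced pipeline (3 PCA components, fixed t = 2, 2-D,
2 k-means restarts) — the calibration is about exchangeability, which any
fixed pipeline preserves. Gap-statistic selection uses 7 blobs × 50 points
with 20 uniform references.

Tolerances: stage outputs are tested against literal-formula oracles at
1e-12 on small instances; row-stochasticity at 1e-10 under powering; MDS
recovery of an exactly realizable square at 1%; stochastic recovery checks
use 3 binomial SE. The probability floor in the log-potential (1e-12), the
strict-inequality threshold rule, k-means tie behaviour (scikit-learn
re-seeds emptied clusters from the farthest points) and the knee rule (max
distance to chord, ties to the smaller index) are fixed conventions chosen
for determinism rather than tuned values.

## Known limitations

* Memory: the embedding materialises U × U matrices; beyond ~10⁴ unique
  patterns, landmark or compression approximations (not implemented) would
  be needed.
* The von Neumann entropy knee is a heuristic; t is overridable and should
  be scanned when results look sensitive to it.
* No multiple-testing correction is applied to significance maps by design
  (matching the analysis the package reproduces); a Benjamini–Hochberg
  variant would be a straightforward extension.
* The CLI's `null --model regions` re-runs the embedding per permutation;
  at 10 000 permutations this is expensive, and the command warns
  accordingly.
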