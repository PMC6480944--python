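# Methods

`gicasel` implements a discriminative-region pipeline for two-group
task-fMRI studies: group independent component analysis (GICA) decomposes
multi-subject data into spatial networks, each network is summarized by five
statistics per atlas region, and a Fisher-discriminant-ratio (FDR)-guided
forward selection under leave-one-out cross-validation (LOOCV) identifies
the feature subsets — and hence the brain regions — that best separate the
groups. A seeded synthetic-cohort generator reproduces the statistical
structure the analysis assumes, so the whole chain is testable without any
restricted clinical data.

## The emulated study design

The generator models a Sternberg item-recognition working-memory experiment:
two groups (34 healthy controls, 34 patients; labels −1 and +1), three runs
per subject, TR 2 s, 180 volumes per 6-minute run. Each run contains two
blocks of each memory-load condition (1, 3 or 5 digits) in seeded
pseudorandom order, alternating with seven fixation epochs. The protocol
fixes the block structure but not the fixation duration; the generator
defaults to 6 TRs (12 s) of fixation, leaving (180 − 42)/6 = 23 TRs (46 s)
per task block, and exposes the fixation length as a parameter. Boxcar
regressors are convolved with a canonical double-gamma hemodynamic response
(peak 6 s, undershoot 16 s, 1:6 amplitude ratio) because the protocol names
the timing but no response model.

## Synthetic volumes

A subject-run volume is

    x(v, t) = sum_k a_k(t) * g_sr(v) * m(v) * s_k(v) + eps(v, t)

* `s_k` — spatially independent source maps: atlas regions are dealt
  round-robin into disjoint per-source supports and filled with zero-mean
  unit-scale Laplace loadings (super-Gaussian, as Infomax assumes). Disjoint
  supports keep pairwise map correlations below 0.2 by construction.
* `a_k(t)` — source time courses: one HRF-convolved load regressor plus a
  slow cosine drift (weight 0.4) plus white innovation (weight 0.9),
  standardized to unit variance. The innovation term is essential: sources
  sharing a load regressor would otherwise be temporally collinear and the
  MDL criterion would merge them.
* `g_sr` — per-subject, per-region gain `1 + N(0, 0.1)`: between-subject
  regional amplitude variability. It is independent across regions, so
  different regional features carry partly independent noise. (A single
  global gain per subject would make the between-subject noise rank-1 and
  cap every classifier at single-feature accuracy.)
* `m(v)` — the planted group effect: `1 + effect_size` inside the designated
  effect regions for patients, 1 otherwise. The default `effect_size = 0.22`
  solves `d = e / (gain_sd * sqrt((1 + (1+e)^2)/2)) = 2`, i.e. the planted
  regional feature separates the groups at a Cohen's d of about 2; the
  end-to-end measured d (after ICA and back-reconstruction) comes out ~1.9.
* `eps` — i.i.d. Gaussian noise (sd 0.5 by default; per-voxel SNR ≈ 8 inside
  the brain mask), optionally AR(1) in time.

The synthetic atlas partitions an ellipsoidal brain mask into seeded-Voronoi
regions; with 116 regions the embedded AAL name table is attached so
reports read like standard anatomical tables. What the generator does *not*
emulate: MRI physics (motion, distortion, physiological noise), spatial
autocorrelation beyond region-shaped sources, hemodynamic variability across
regions, and behavioral responses. Passing tests therefore demonstrate that
the pipeline recovers the statistical structure it targets, not that it
would perform identically on scanner data.

## Group ICA

1. **Model order.** The number of components is estimated per run by a
   minimum-description-length criterion on the eigenvalues of the temporal
   sample covariance (voxels as samples),

       MDL(k) = −N′(p−k)·log(g_k/a_k) + ½·k·(2p−k+1)·log N′,

   where `g_k`/`a_k` are geometric/arithmetic means of the `p−k` smallest
   eigenvalues. Because smoothed fMRI voxels are not independent samples,
   the effective sample size N′ counts only every second voxel per axis
   (stride configurable) — the "modified" element of the criterion.
   Eigenvalues come from the full covariance; only N′ is corrected, which
   keeps the criterion well-conditioned on small grids. The group order is
   the median of per-run estimates.
2. **Reduction.** Each run (voxel time series mean-centred; variance
   normalization optional and off by default) is PCA-reduced to
   `k1 = min(2k, T)` temporal components — headroom above the target order
   `k`; the reduced runs are concatenated and group-PCA-reduced to `k`.
3. **Infomax ICA.** Full-batch natural-gradient ascent with the logistic
   nonlinearity, `ΔW = η(I + (1−2y)uᵀ)W`, on symmetric-whitened data.
   The step size (default 0.05) anneals by 0.9 whenever the update direction
   turns by more than 60°; iteration stops when ‖ΔW‖_F < 1e−6 or after 2048
   iterations (shorter fixed-step budgets demonstrably stall short of
   separation). Divergence restarts with a halved initial rate, up to 5
   times. All starts are seeded.
4. **Back-reconstruction.** Subject-run maps are recovered by GICA
   back-projection: the pseudo-inverse of the run's block of the group
   mixing matrix applied to the run's reduced data. The map/time-course
   scale split is arbitrary, so each component's time course is normalized
   to unit variance and the amplitude moved into the map — otherwise
   per-subject amplitude differences (the quantity of interest) are absorbed
   into the mixing blocks and never reach the regional features. Per-subject
   maps are the average over that subject's runs; components are index-wise
   common across runs under a single group decomposition, so the average
   needs no matching step. Component sign is canonicalized by making the
   maximal-|value| voxel of each group map positive.

One contract choice deserves note: the pipeline runs a single GICA over all
subject-runs and averages the back-reconstructed maps per subject, rather
than decomposing runs separately.

## Regional features

Each subject's map for one component is segmented by the atlas (labels
1..n_regions, ascending; background excluded) and summarized per region by
mean, standard deviation, skewness, kurtosis and entropy, in that column
order, region-major: with 116 regions, 580 columns per component. Moments
use the population (÷N) convention; kurtosis is raw (Normal ≈ 3). Entropy
uses a 256-bin equal-width histogram over [min, max] (bin count
configurable), skipping empty bins. Degenerate regions (constant or single
voxel) report zero shape statistics with a logged warning; an absent region
is an error in strict mode or five zero features with `--allow-empty-regions`.
Statistics are computed on raw map values by default; per-map z-scoring is
togglable.

## Selection and classification

Per outer LOOCV fold (one held-out subject):

1. Features are ranked on the training rows by the Fisher discriminant
   ratio `|mean_h − mean_s|² / (var_h + var_s)` (population variances;
   zero-denominator features rank first when their means differ). Ties
   break by ascending column index.
2. Ranked features are added one at a time up to `max_subset`
   (default min(50, p); the studies in the tests use 10); each prefix is
   scored by an inner LOOCV on the training rows with the chosen
   classifier. The smallest prefix attaining the maximal inner accuracy is
   selected — smallest-subset tie-break.
3. The fold's model trains on the chosen subset and predicts the held-out
   subject. Accuracy is the percentage of correct held-out predictions,
   reported to one decimal.

Classifiers are scikit-learn's C-SVC with linear kernel (default C = 1.09;
the canonical sweep 0.01–1000 in powers of 10 is carried on the classifier
configuration object) and 1-nearest-neighbour with
Euclidean distance. Each fold z-scores feature columns by its training
rows' statistics before classification (standard practice for C-SVC — a
fixed C is meaningless across arbitrary feature scales); FDR ranking is
scale-invariant, so the ranking is unaffected. Two exact fast paths keep
the inner LOOCV tractable: 1-NN accuracy traces use a cumulative distance
matrix, and SVM leave-one-out uses the KKT fact that removing a
zero-dual-coefficient point leaves the solution unchanged, so only support
vectors are refit. Both paths are asserted equal to brute-force refits in
the test suite.

The literal reading of the protocol — choose the subset that classifies the
*held-out* sample best — leaks the test label and is implemented only
behind `literal_selection=True` for comparison; a test demonstrates its
optimistic bias on pure noise. The default protocol keeps the held-out
subject out of ranking, selection and scaling, which the taint test
enforces. Repeats (`n_repeats`) shuffle fold evaluation order under the
seed; the default protocol is deterministic given the data, so repeated
accuracies are identical and the spread is zero — repeats exist to expose
order-dependence, and seeded variation enters through cohort generation
instead.

## Region report

Selected feature columns map back through the column descriptors to
(region, statistic) pairs; regions de-duplicate per component with
fold-selection frequencies (a fold counts once however many of a region's
statistics it selects). Across components, a region is "frequently
occurring" when at least ⌈n_ICs/2⌉ components select it (threshold
configurable); outputs are per-component TSV tables, a cross-component
frequency table, a NIfTI label mask of the frequent regions, and a Markdown
summary. Report generation from persisted per-fold outputs is
deterministic and byte-stable.

## Problem sizes used in tests and the acceptance script

The full-study grid (53 × 63 × 46 at 3 mm) is the generator default, but
the shipped studies run on reduced grids chosen as the package's own test
conditions: 16 × 18 × 14 with 180 timepoints, 24 regions and 4 sources for
the 34+34 pipeline study; 20 × 22 × 18 with 26 regions for the 13-source
MDL study; 10 × 12 × 8 with 48 timepoints for unit-level cohorts. These
keep the planted structure (block design, disjoint region-supported
sources, calibrated d ≈ 2 effect) while fitting a single CPU.

## Known limitations

* The MDL effective-sample correction is a stride-based approximation, not
  a smoothness-estimated one; on strongly smoothed data the stride should
  be raised to match the kernel width.
* Infomax with the logistic nonlinearity assumes super-Gaussian sources
  (true of the generator and typical of fMRI spatial maps); sub-Gaussian
  sources would need the extended variant, which is out of scope.
* The amplitude-preserving back-reconstruction convention (unit-variance
  time courses) is one of several defensible scale conventions; analyses
  comparing map amplitudes across pipelines should confirm the convention
  matches.
* Accuracy estimates from LOOCV with per-fold selection are unbiased for
  the selection-inclusive procedure but remain high-variance at n = 68;
  the permutation-null test bounds the optimism of the default protocol.
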