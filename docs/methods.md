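# Methods

This note documents the models, numerical choices and known limitations of
the `dfcp` pipeline, in the order the method runs.

## Connectivity

Static FC is the sample Pearson correlation over all T time points with a
zero diagonal. ROI series are used as-is: Pearson correlation is invariant
to per-ROI affine rescaling, so detrending/z-scoring of individual series
does not change any downstream quantity and is deliberately left out of
the pipeline's responsibilities.

Static strength defaults to the **positive sum** `Σ_j max(Corr_ij, 0)` —
the explicit formula definition — with the absolute-value variant
(`Σ_j |Corr_ij|`) available via `mode="absolute_sum"`, since both
conventions circulate for this statistic; the mode is recorded in every
strength vector.

Window lengths are specified in **seconds** and converted per subject as
`round(w/TR)` samples (minimum 2). This lets cohorts acquired at different
TRs (e.g. 3.0 s cases vs 2.0 s controls) share the same nominal window —
the cross-scanner setting the method is designed for. The slide step is 1
sample. Tapered windows and regularized covariance estimators are out of
scope.

A zero-variance ROI column (flat signal) within the full scan or a window
gets zero correlations and a `DfcpWarning` instead of propagating NaN;
this keeps the dFCS matrix inside its [0, N−1] bounds and only arises for
degenerate inputs.

## Segmentation

Adjacent dFCS columns are compared by Euclidean distance; a boundary is
declared after window t when `d_t > mean(d) + α·std(d)` (strict, so an
all-equal distance series yields one segment). Defaults: α = 1.0, minimum
segment length 2 windows. Undersized segments are merged into the
neighbour across the weaker boundary; ties merge left. The rule is scale
invariant (mean and std scale together) and exact on high-SNR
piecewise-constant inputs (verified over 100 seeds in the acceptance
suite). Formal change-point methods (PELT, binary segmentation) are
intentionally not used: the adjacent-distance threshold is the method this
pipeline implements.

## Twice-clustering and pattern count

Stage 1 overclusters the pooled training WQCPs with K-means
(`k0 = min(2·⌈√n⌉, n)` by default, 10 restarts, seeded); stage 2 builds a
Ward dendrogram over the k0 K-means centroids and cuts it at every
candidate K. Each cut relabels the WQCPs through their stage-1 cluster,
and the elbow curve records the total within-cluster sum of squares of the
WQCPs themselves (not of the centroids). K is the candidate maximizing the
perpendicular distance from the chord joining the curve's endpoints; ties
take the smaller K. Candidates default to 1–10: starting the scan at K=1
is essential, otherwise a true two-state structure has no visible knee.
Final centroids are member means; if dendrogram ties yield fewer than K
distinct clusters (e.g. all-identical WQCPs) the centroid matrix is padded
with the grand mean so the model carries the selected K.

Clustering is pooled across training groups (one model for both), which is
what the train/test feature pathway requires; a per-group variant would
need a rule for aligning pattern indices across groups and is not
implemented.

## Features

Ratio features divide per-pattern WQCP counts by the subject's total WQCP
count — the only normalization that makes them a distribution. Beta
features are ordinary least squares without intercept (the pattern model
is a pure linear combination); rank-deficient centroid sets fall back to
the minimum-norm solution. **One code path serves training and test
subjects**: features always use nearest-centroid assignment (ties to the
lowest index), never the clustering's internal labels, so a subject's
features do not depend on which side of the split it fell on. A subject
with zero WQCPs (impossible for valid inputs, possible for pathological
configs) gets zeroed, flagged features and a warning.

## Selection and classification

Features are z-scored with training-split statistics before selection —
RFE weight ranking is meaningless across unscaled heterogeneous blocks
(occupancy ratios vs strength sums). SVM-RFE eliminates the `rfe_step=1`
features with the smallest squared linear-SVM weights per round (C = 1);
the retained subset is the ranking prefix with the best inner-CV accuracy,
ties to the smaller subset (a fixed subset size is available via config).
The final SVM defaults to the RBF kernel with log-2 grids C ∈ 2⁻⁵..2⁵ and
γ ∈ 2⁻⁷..2¹ — tuning γ only makes sense for a nonlinear kernel, and both
kernel and grids are configurable (linear mode tunes C only). Grid ties
prefer the smallest C, then the smallest γ.

The outer protocol is stratified 5-fold CV repeated 20 times (100 runs) by
default; per-group fold sizes differ by at most one. All child seeds
(folds, clustering, inner CV) derive from the master seed via
`SeedSequence`, making the whole protocol bit-reproducible. A hard
leakage guard raises if any held-out subject's WQCPs reach the clustering
step. An optional fully-held-out second control cohort can be scored by
every fold's trained classifier.

Metrics treat the case (patient) group as positive. Zero-denominator
metrics are reported as 0 and flagged rather than NaN. Aggregation uses
the sample standard deviation and a t-based 95% CI; approach comparisons
use the pooled-variance two-sample t-test (Welch optional); window
sensitivity is the Pearson correlation between window lengths and the
per-window metric *means* (this is the reading that reproduces the
published sensitivity coefficients from the published per-window means).

## Synthetic cohorts

The generator emulates exactly the second-order structure the pipeline
consumes; it does not model hemodynamics, physiological noise or scanner
drift, and makes no claim about spatial realism. Passing tests therefore
demonstrate method correctness and sensitivity under the planted model,
not performance on real fMRI.

* **States.** Each of K latent states is a correlation matrix built from
  low-rank factor loadings plus unit uniqueness. States model **hub
  reconfiguration**: ROIs are split into K blocks and state k gives block
  k strong loadings (scale 2.0) against a weak background (0.3). This
  makes states differ in their per-ROI strength profiles — the projection
  the dFCS pipeline actually sees — with ≈3 sd separation at the
  single-window level for the default 20-ROI, 12-sample-window setting.
  States are resampled until pairwise Frobenius distance ≥ 2.
* **Dynamics.** A minimum-dwell Markov chain with stationary occupancy
  (0.7, 0.3) for cases and (0.3, 0.7) for controls; `dwell_min = 5`
  samples, `switch_rate = 0.4` (expected dwells ≈ 9–13 samples, ≈ 12–15
  state visits per T=150 scan). This regime was chosen by an
  identifiability analysis: per-subject occupancy must be estimable from
  one scan (favoring many visits), while dwells remain on the order of
  the analysis window. Longer dwells starve the occupancy estimate (with
  dwell ≈ 27 samples, even ground-truth occupancy classifies at only
  ~0.90); the chosen regime puts the ground-truth ceiling at ~0.96–0.99.
  A consequence worth knowing: at T=150 many windows straddle state
  switches, so segments measure state *composition* rather than pure
  states — the occupancy signal survives, but this is the main noise
  source in the dynamic features.
* **Group effects.** Besides the occupancy difference, cases get a static
  strength offset: the loadings of a designated informative ROI subset
  (4 of 20 by default) are scaled by 1 + 0.3.
* **Emissions.** Zero-mean Gaussians with the dwelling state's
  correlation matrix plus isotropic noise (sd 0.1).
* **Presets.** `strong-effect` (the defaults above; 34+34 subjects,
  T=150 at TR 2.0 s, 20 ROIs), `null` (identical occupancies 0.5/0.5, no
  shift — classification should sit at chance), and `paper-shaped`
  (246 ROIs, cases at TR 3.0 s with T=150 vs controls at 2.0 s with
  T=130, emulating a heterogeneous-scanner study's shape).

Everything derives from the master seed; cohorts are bit-reproducible.

## Problem sizes

The test and acceptance suites run the full protocol at 20 ROIs, 34+34
subjects, T=150, 24 s windows, 5 repeats × 5 folds (25 runs per
approach) — sizes chosen so the entire validation executes on a laptop
CPU in a few minutes while keeping the cohort geometry of a single-site
study. Unit-level oracles use smaller randomized instances (≤ 40×6
series, ≤ 100 WQCPs).

## Known limitations

* The segmentation threshold (`mean + α·std`) is a global rule; slow
  drifts or heteroscedastic noise across the scan can bias boundary
  placement.
* Ratio features count segments, not time: when segment lengths vary
  systematically between groups this estimator of occupancy is biased.
  With the default segmentation producing many short segments the effect
  is small.
* The elbow rule needs a curve that actually bends; on flat curves it
  defaults to small K, which is conservative.
* With short scans (T ≈ 150) and dwell times near the window length, the
  dynamic features are composition estimates (see above); accuracy
  saturates below the ground-truth occupancy ceiling.
* The generator's Gaussian, piecewise-stationary model contains no
  hemodynamic response, motion, or 1/f noise; real-data performance
  claims cannot be made from it.
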