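# Methods

## The problem

Brain-age models regress chronological age on neuroimaging features and
interpret the residual — the brain-age gap (BAG = true age − predicted
age) — as an index of atypical maturation. In developmental reading
research the maturational-lag hypothesis predicts that poor readers'
functional networks resemble those of younger children, so an age model
trained on functional connectivity (FC) should systematically
*under*-estimate their age (positive BAG). This package implements that
full analysis chain and, because the motivating cohort data sit behind a
data-usage agreement, pairs it with a synthetic cohort generator that
plants the statistical structure the analysis assumes, so every stage is
testable end to end.

## Prediction model

Features are the Fisher z-transformed Pearson correlations between all
ROI pairs of a parcellation, vectorized in a fixed canonical order
((i, j), i < j, row-major; C(n, 2) edges — 79,800 for 400 ROIs).
For each of `n_permutations` permutations:

1. **Stratified 2:1 split.** Within each reading group, a random third
   (floor(n_g/3)) is held out; groups are recombined so both halves keep
   the group proportions. With group sizes 193/338/211 this yields
   496 train / 246 test.
2. **PCA on the training rows only**, keeping the minimal number of
   components whose cumulative explained variance reaches 95%.
3. **Linear SVR** (ε = 0.1 years, C = 1.0) on the component scores.
   Reading ability never enters fitting.
4. **5-fold CV inside the training set** (folds stratified by reading
   group), recording fold MAEs of raw predictions.
5. **Hold-out prediction**, then rescaling: raw test predictions are
   z-scored against their own mean/SD, multiplied by the cohort age SD
   and shifted to the cohort mean age, which puts predictions on the age
   scale without changing their ordering.

Per-subject predictions and absolute errors are averaged over the
permutations in which the subject was held out. Stability is the
coefficient of variation (100·SD/mean) of per-permutation test MAEs.
CV significance shuffles training ages and repeats the CV procedure; the
p-value uses the add-one estimator (1 + #{null ≤ observed})/(1 + n_null),
so it is never exactly zero. Models are compared by two-sided Wilcoxon
signed-rank tests on paired subject-level MAEs, with Cohen's d of the
paired differences.

Numerical choices: correlations are clipped at 1 − 1e−7 before arctanh;
a constant raw prediction vector rescales to the mean age; component
selection uses "smallest k with cumulative variance ≥ 0.95" (made
explicit rather than relying on a library's tie convention); the SVR
regularization constant C is not pinned down by the design, so it is 1.0
and exposed as a parameter. Seeding: the ensemble spawns one
`SeedSequence` child per permutation, so any single permutation is
independently reproducible.

### Rescaling scope

Whether the z-scoring of raw predictions should use each permutation's
own prediction set or the pool across permutations is genuinely open;
the default standardizes per permutation (each permutation is an
independent model realization), with `rescale_scope="pooled"` as the
alternative. MAE after rescaling is invariant to affine transforms of
the raw predictions, which the tests assert.

## Weight interpretation

Each member's SVR weight vector (1 × N in component space) is multiplied
through its PCA component matrix (N × M) to give one weight per
connection; these are averaged over the ensemble. The central
correctness property is the linear-equivalence oracle: for any input,
edge-space prediction (w_edge·(x − mean) + b) equals the component-space
prediction to 1e−8 relative — asserted on freshly fitted models.

Edge significance shuffles the averaged coefficient vector across edge
positions (2500 draws) and compares each position's observed
|coefficient| with the shuffled values landing there; because the
shuffles are exchangeable this equals pooling the coefficient
distribution. Significance is one-sided on |coefficient| (importance
framing), uncorrected at α = .05 by design — the downstream ROI test
carries the strict correction. Significant edges are decomposed into
their endpoint ROIs; ROI overrepresentation is tested against 2500
with-replacement uniform draws of the same number of ROI slots
(α = .0001), and network-level shares reuse the identical null draws,
which automatically reflect each network's spatial extent. Two-sided
network p-values report direction (over/under). An edge-class census
(within/between-network × left/right/interhemispheric) compares
significant-set rates with whole-matrix rates.

## Brain-age-gap inference

BAG = true − predicted (positive = underestimation). Because
predictions compress the age range, BAG correlates positively with true
age even for unbiased models (regression to the mean, asserted in the
tests), so age is always a covariate. The mixed-design RM-ANCOVA treats
the ROI-set model as the within-subject factor and group, age,
group × age, and nuisance covariates (gender, SES, PIQ, handedness) as
between-subject terms. It is computed in two parts that together
reproduce the classical mixed-design partition: between-subject effects
by type-III OLS on subject-mean BAG (e.g. Group df = (2, n − 6) with
age and group × age in the model), and within-subject effects (Model,
Model × Group) on the repeated measures with Greenhouse-Geisser
correction applied when Mauchly's test rejects sphericity (the epsilon
from the within factor is applied to both within-subject terms).
Covariates enter as between-subject main effects only; rows with
missing covariates are dropped listwise and the count is reported. A
degenerate within factor (identical bags across models) short-circuits
to F = 0, p = 1 rather than attempting sphericity estimation on a
singular covariance.

Age bins follow the ladder 6–8, 8–9.5, 9.5–11, 11–13, 13–15, 15–21
years, left-closed/right-open with an inclusive top, so a boundary age
belongs to the higher bin; bin membership counts are reported.
Continuous-skill regressions standardize BAG, age, the reading index,
and their (raw-product, then standardized) interaction, so coefficients
are standardized betas; when the interaction is significant, per-bin
simple-effects regressions re-standardize within bin (flagged in the
output as such).

## Synthetic cohort generator

The generator is first-class, tested code. It emulates:

- **Groups.** Poor/typical/exceptional readers defined by the reading
  composite (mean of two subtest standard scores): < 91 / 91–109 / > 109.
  Group sizes come from largest-remainder apportionment, which is
  deterministic and sum-preserving and reproduces 193/338/211 at the
  study's proportions. Subtest scores are truncated normals at the
  group-specific means/SDs (e.g. poor readers ≈ 76/78 ± 9/10), rejection-
  sampled (cap 1000) until the composite obeys the cutoff — groups are
  defined by cutoffs, not by a distribution, so rejection sampling is the
  faithful mechanism.
- **Ages.** A truncated skew-normal (shape 3, loc 7.5, scale 4.5) on
  [6, 21], favoring 8–12 years as in community developmental samples;
  the shape is configurable.
- **Covariates.** Gender, handedness (Bernoulli at group-specific
  rates), SES and performance IQ (rounded truncated normals), with
  group-specific missingness in SES/PIQ so that listwise-deletion paths
  are exercised.
- **Parcellation.** Even L/R split; seven networks in fixed unequal
  proportions with Default and Control largest; centroids in a
  brain-sized box with hemisphere-signed x.
- **Connectivity.** z(e, p) = baseline(e) + slope(e)·(effective_age − age
  midpoint) + N(0, σ). Within-network baselines exceed between-network
  ones. A fraction of edges (default 10%) is developmental:
  within-Default/Control edges strengthen (+0.02 z/yr by default),
  Default↔Control edges grow more negative, any remainder gets
  half-magnitude slopes of random sign. Noise σ defaults to 0.10 z.
- **Maturational lag.** Effective age = age − δ (poor), +δ (exceptional)
  on the lag scope. The true direction and size of any group effect is
  unknown — the motivating study's own results are mixed — so δ is a free
  simulation parameter defaulting to 0, with
  `lag_scope="reading_network_edges"` as the default hypothesis and
  `"all_edges"` for whole-brain-lag experiments.
- **Coordinates.** A synthetic meta-analysis list (416 points, 49
  out-of-range by construction) clustered on Default/Control/
  Salience-preferred, left-biased ROIs with Zipf-like multiplicity, so
  the minimum-hit-count cutoffs (k = 0/1/2/4) yield a nested ROI ladder.
  Synthetic coordinate-to-ROI mapping is nearest-centroid within 12 mm
  (ties to the lowest id, flagged); volumetric containment in a labeled
  template is the optional real-data path behind the same interface.

What the generator does **not** emulate: BOLD time-series realism
(hemodynamics, autocorrelation, motion), scanner quality control,
spatial autocorrelation between neighboring ROIs, or any nonlinear
developmental trajectory. Passing tests therefore demonstrate that the
machinery is correct and calibrated under the planted linear model, not
that the scientific findings on real data would replicate.

## Validation experiments and problem sizes

The validation suite (and the reproduction script) uses scaled-down
study conditions chosen to run in minutes on one CPU:

- **Signal recovery:** n = 450, 100 ROIs (4950 edges), 1% developmental
  edges at 0.02 z/yr, noise 0.10 z, 100 permutations. The ensemble's
  test MAE must undercut the no-signal reference (mean absolute
  deviation from the mean age, which is what the rescaling rule outputs
  when features carry no information) by at least 25%, and the planted
  edges' mean |coefficient| rank must land in the top 5%.
- **Null calibration:** 20 no-signal cohorts (n = 60, 16 ROIs) × 200
  label-shuffle nulls — CV p-values uniform (KS test); edge-flag rate ≈
  α on exchangeable coefficients; Group-effect type-I rate ≈ α at δ = 0
  over 20 end-to-end runs.
- **Directional BAG recovery:** δ = 1.5 yr on all edges, n = 150,
  24 ROIs, 30 permutations, two ROI-set models; mean BAG must order
  PR > TR > ER in ≥ 8 of 10 seeded runs.

## Known limitations

- Synthetic "containment" is nearest-centroid, not volumetric; real
  parcellation volumes change which coordinates map where.
- The generator's linear age model cannot probe nonlinear maturation,
  and its i.i.d. edge noise understates the spatial correlation of real
  FC, making PCA more effective than it would be on real data.
- The RM-ANCOVA's between/within partition assumes covariates do not
  interact with the within-subject factor (covariates are
  between-subject main effects only).
- SVR convergence slows markedly on pure-noise features at large n;
  null-calibration experiments are therefore run at small n, which is
  also where their statistical behavior is hardest (most conservative).
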