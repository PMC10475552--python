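# Methods

This note records the models, conventions and design choices behind
`dynstates`, and what the synthetic-cohort experiments do and do not
demonstrate about real data.

## Synthetic cohort model

Each subject carries a hidden two-state Markov chain at timepoint (TR)
resolution. State 1 is a strongly coupled connectivity regime, state 2 a
weakly coupled one. Component signals at timepoint *t* are zero-mean
multivariate normal draws with the covariance of the current state:

* State 1: within-network off-diagonal correlation 0.6, between-network
  0.3, unit diagonal (block structure over the 7 cortical networks with
  component counts 6, 3, 2, 2, 1, 2, 4).
* State 2: all off-diagonals scaled by 0.25.

Both matrices are positive definite by construction (a nonnegative sum of
block terms plus a positive diagonal). Innovations carry AR(1) temporal
correlation ρ = 0.4, the typical grey-matter BOLD lag-1 autocorrelation at
TR = 2 s; the marginal cross-sectional covariance is unchanged, but the
spectrum becomes low-frequency weighted (≈ 34 % of power above 0.1 Hz) so
that genuine components pass the spectral artifact screen, as in real data.
White observation noise of SD 0.5 is added on top of the unit-variance
signals.

**Dwell calibration.** Group stay probabilities are derived from published
window-resolution mean dwell times for two-state solutions in paediatric
generalised epilepsy via `p ≈ 1 − 1/MDT`: patients (0.920, 0.981), controls
(0.965, 0.977). These imply stationary state-1 occupancies of 0.19
(patients) vs 0.40 (controls) — the occupancy gap the pipeline is designed
to detect. Epilepsy duration (uniform 1–120 months) is coupled linearly to
each patient's state-1 stay probability, with the coefficient (0.16 over
the duration range) calibrated so the planted duration ↔ state-1-occupancy
partial correlation sits near the ≈ 0.5 reported for such cohorts. Ages
are uniform 24–144 months and sex Bernoulli(1/2).

**Voxel model.** Each component is a truncated Gaussian blob (σ = 1 voxel,
support strictly inside radius 2) on a disjoint lattice in a 20×20×10 grid;
maps have unit L2 norm. Voxel data are `timecourses @ maps` plus white
noise of SD 0.1 — with unit-norm maps the peak blob voxel is ≈ 0.17, so
this is a peak contrast-to-noise ratio of ≈ 1.7, typical of BOLD networks.
The 7-network label template paints each blob with its network's integer
label. Motion traces are random walks (0.02 mm/step translations, 20×
smaller rotations, occasional 0.3 mm spikes), producing mean FD ≈ 0.1 mm
and, by design, no excluded subjects — matching a cohort screened to have
none.

**Ground-truth window labels.** Hidden states switch at TR resolution;
sliding windows therefore straddle transitions. The truth label of a window
is the state occupying the majority of its TRs (ties toward state 1),
matching how windowing blurs transitions in real data.

What the generator does **not** emulate: scanner drift and physiological
noise spectra, spatial autocorrelation of noise, subject-specific spatial
topography, haemodynamic convolution, and spatial misregistration. Tests
passing on this model therefore validate the estimators' correctness and
calibration, not their robustness to those real-data nuisances.

## Motion QC conventions

FD is the Power-style sum of absolute backward differences with a 50 mm
sphere radius for rotations; input rotations are radians (a flag accepts
degrees). Exclusion: mean FD ≥ 0.5 mm (boundary inclusive), strictly more
than 20 % of timepoints with FD > 0.5 mm, or any realignment parameter
beyond 3 mm / 3° relative to the reference volume (read as per-parameter
absolute displacement, not per-frame increments). Frames are never
censored; exclusion operates on whole subjects.

## Group ICA

Two-stage reduction: per-voxel variance normalisation (switchable), subject
temporal PCA to 40 dimensions (the model order must be coverable; 40 ≥ 26),
concatenation, group PCA to the model order, and whitening to unit row RMS
(rows are orthogonal, so the second-moment matrix is exactly identity).
Rank below the requested dimension raises with the achieved rank.

Infomax uses the natural-gradient update with a logistic score over
shuffled sample blocks, geometric learning-rate annealing (0.97/sweep,
halving on divergence), tolerance 1e-6 on the per-sweep weight change, at
most 500 sweeps; non-convergence flags the result rather than raising. The
logistic score recovers super-Gaussian (sparse, heavy-tailed) sources —
the regime of spatial brain maps; sub-Gaussian sources are out of scope.

Stability follows the multi-run aggregation idea in simplified form: the
first run is the reference, other runs are matched one-to-one by maximal
|spatial correlation| (Hungarian assignment), sign-aligned and averaged;
the stability index is the mean |correlation| of members with the
aggregate. Full centrotype clustering is intentionally not implemented.
Aggregate maps are sign-oriented (peak voxel positive — ICA signs are
arbitrary) and z-scored across voxels; `ReductionModel.voxel_scale` returns
them to data units when comparisons against raw mixing maps are needed.
Back-reconstruction is dual regression (spatial then temporal regression on
demeaned subject data); the GICA back-projection variant is not provided,
and the choice is recorded in the run manifest.

## Component selection and cleaning

Template matching correlates each IC map with each network's binary
indicator; for disjoint templates this ranks identically to the regression
formulation. Retention threshold 0.2; a component matching several
networks gets the argmax label only. The spectral screen flags components
with more than half their non-DC periodogram power above 0.1 Hz, replacing
visual artifact inspection with a deterministic rule; YAML keep/drop
overrides emulate manual curation. Cleaning order is fixed: linear detrend
→ OLS residualisation on the Friston-24 regressors (6 parameters, their
lags zero-padded at t = 1, and both squared) → zero-phase 4th-order
Butterworth band-pass 0.01–0.1 Hz. Cleaning is idempotent to < 1 % RMS
for mid-band content once the series is long enough for filter edge
transients to clear the central 80 %; band-edge content is attenuated
further on re-filtering, which is why the pipeline cleans exactly once.

## Static and dynamic connectivity

Perfect correlations are clipped at atanh(1 − 1e-7) rather than propagating
infinities. The edge-wise GLM `z ~ intercept + group + age + sex` (group
0 = control, 1 = patient, so negative effects mean patient < control) is
solved in closed form across all edges at once and is verified against
statsmodels per-edge fits in the tests; significance is the uncorrected
two-sided p against α = 0.01, with Benjamini–Hochberg q-values reported
alongside.

Window count follows `floor((T − width)/step)` — the convention under which
120 post-discard timepoints with 30-TR windows and step 1 give exactly 90
windows (the last window stops one timepoint short; the common
`T − W + 1` convention would give 91). The robustness rerun uses width 40
(80 windows). Clustering operates on Fisher-z edge vectors by default;
clustering on raw r was evaluated against the synthetic ground truth and
recovers slightly worse, so z stays the default. k-means uses squared
Euclidean distance (cityblock/median clustering available by flag, sharing
the silhouette metric), best of 100 random initialisations under a master
seed; silhouette selection scans k = 2..10 with a smaller per-k
initialisation budget. States are relabelled by descending mean centroid
connectivity so "State 1 = strong" is stable across runs and seeds; empty
clusters trigger a reseeded retry with a capped count.

## Temporal metrics and inference

A state never visited contributes a mean dwell time of 0 (not a missing
value): published group summaries whose SDs exceed their means are only
consistent with zeros being included, and a flag switches to exclusion.
Group comparisons use the covariate-adjusted GLM rather than a plain
two-sample t, since "controlling for age and sex" requires covariates in
the model. Duration correlations are partial Pearson correlations after
residualising both variables on age and sex, with
`t = r·sqrt((n−2−c)/(1−r²))` on n − 2 − c degrees of freedom; pingouin's
`partial_corr` serves as an independent oracle in the tests. The Welch
(unequal-variance) form is the default for summary-statistic group
comparisons and the sex table uses the uncorrected Pearson chi-square —
the variants that reproduce published values from printed summaries; pooled
t and Yates correction are available by flag.

## Problem sizes in tests and the acceptance script

Recovery experiments run at the study scale (55 subjects, 120 timepoints,
20 components, 90 windows) where the cohort-level statistics are the
point, and at reduced scale where they are not: model-order selection uses
20-subject cohorts over 10 replicates, ICA recovery uses a 6-subject
noiseless cohort at model order 20 (a noiseless cohort has exactly rank-20
data, so requesting 26 would be rank-deficient by construction), GLM
calibration uses 500 null replicates of the full 55 × 190 edge design, and
the directional-pattern check uses 20 seeded 55-subject cohorts. These
sizes make the whole suite run in minutes while keeping every statistical
claim at or above the sample sizes it concerns.

## Known limitations

* The structural ceiling on window-label recovery: with dwell times
  calibrated to published values, ≈ 10 % of 30-TR windows straddle
  transitions and are intrinsically ambiguous; a nearest-centroid oracle
  using the true pure-state correlation vectors scores *below* the fitted
  k-means on the same windows (0.87 vs 0.90). Agreement near 0.90 is
  therefore the attainable level at these conditions, not an estimator
  defect.
* Infomax is the only ICA flavour; model order is user-fixed, never
  estimated.
* No tapered windows, regularised covariance, HMM state models or
  meta-state analyses; no frame censoring; no graph-theoretic summaries.
* Publication-grade circular connectivity graphics are out of scope; the
  pipeline emits ranked edge lists instead.
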