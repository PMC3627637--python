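# Methods

## The measurement model

All metrics are histogram-level summaries of the segmented lung voxels of
two separately acquired breath-holds (full inspiration and end-tidal
expiration). No deformable registration is performed and none is needed:
every paired measure compares whole-lung summaries, not voxel
correspondences. Attenuation is used exactly as stored (after the NIfTI
scale/intercept); no scanner-calibration correction is applied, and values
outside [−1024, 3071] HU produce a warning rather than clamping.

**Threshold conventions.** "Below a threshold" is strict (`HU < t`). The
relative-volume band is `−950 ≤ HU < −856` and its denominator, the lung
without emphysema, is `HU ≥ −950`. With these conventions the emphysema
set, the band, and the denser remainder partition the lung exactly, so
counts are never double-assigned. Voxels exactly at a classification
cut-point (4/5/14/15%) fall in the intermediate class because both defining
inequalities are strict.

**Lung volumes.** Volume = voxel count × product of the three spacing
components (mm³) × 10⁻⁶ L. Volumetric acquisitions are assumed: no
slice-gap or overlap model. The inspiratory volume estimates TLC, the
expiratory volume FRC. An empty mask yields 0 L with a warning; the
composite metric computation refuses a zero TLC.

**E/I MLA stability.** The ratio of mean lung attenuations is refused when
the inspiratory mean is within ±1 HU of zero: a physiological inspiratory
lung mean sits near −850 HU, so a near-zero mean indicates broken input and
an unstable ratio, not a measurement.

## Residualized gas trapping

The fourth gas-trapping measure is the residual vector of the cohort-wide
OLS of Exp₋₈₅₆ on Insp₋₉₅₀, *with intercept* — the intercept is what makes
the residuals mean-zero, matching the measure's defining property of being
exactly uncorrelated with the emphysema index. The fit is a single
cohort-wide regression (not per-stratum); stratified analyses reuse the
cohort-wide residuals. Missing values are excluded pairwise before fitting
and the affected subjects carry NaN residuals, never imputed values.

## Cohort statistics

* Standardization uses the sample (n−1) standard deviation. The choice
  between n and n−1 rescales betas by O(1/n) and leaves fit statistics
  unchanged; n−1 matches the variance estimator used everywhere else in the
  package.
* Correlations are pairwise-complete; regressions are listwise over the
  involved columns, so each model reports its own n.
* p-values are two-sided; no multiple-testing correction is applied.
* Joint outcome models standardize the two CT predictors (and any
  continuous covariates; binary covariates enter as-is) on the analysis
  sample. The default covariate set is empty: the adjusted-model covariate
  lists used in large cohort studies are study-specific, so they are left
  configurable rather than guessed.
* GOLD staging uses the fixed-ratio criteria: obstruction at FEV₁/FVC <
  0.7, staged at 80/50/30% predicted FEV₁; preserved ratio with FEV₁ ≥ 80%
  is GOLD 0 and with reduced FEV₁ is unclassified.
* Rank (Spearman) correlations use mid-ranks for ties, inheriting
  scipy's implementation; duplicate-scan reproducibility requires at least
  three pairs.

## The phantom generator and its oracle

A phantom lung is a filled ellipsoid (semi-axes at 45% of each grid
dimension) whose voxels belong i.i.d. to emphysema / trapped / normal
compartments with fractions (f_emph, f_trap, 1−f_emph−f_trap). Inspiratory
HU are truncated normals on [−1024, 100]:

| compartment | insp mean (HU) | insp SD | expiratory shift (HU) |
|---|---|---|---|
| emphysema | −990 | 15 | +5 |
| trapped | −880 | 20 | +10 |
| normal | −870 | 25 | +150 |

Defaults are chosen so that emphysema sits almost entirely below −950 HU in
both phases, trapped lung stays inside the −950…−856 band on expiration,
and normal lung crosses −856 on expiration — the configuration in which
expiratory lucency alone conflates destroyed parenchyma with closed small
airways. Expiration retains each lung voxel independently with probability
0.65 (the expected FRC/TLC) and adds the compartment shift to the retained
inspiratory draw. Thinning instead of geometric deformation is deliberate:
the paired metrics are histogram-level, so geometry is irrelevant to their
values, and reusing the inspiratory draws keeps the oracle closed-form —
the expiratory tail probability of compartment *c* at threshold *t* is the
inspiratory truncated-normal CDF at (t − shift_c).

Closed-form expectations: E[Insp₋₉₅₀] = 100·Σ_c f_c·F_c(−950);
E[Exp₋₈₅₆] = 100·Σ_c f_c·F_c(−856 − shift_c); E/I MLA as the ratio of the
compartment-weighted expected means; the relative volumes as band
probability over denominator probability per phase. Monte-Carlo standard
errors at the realized voxel counts accompany the expectations: binomial
for the percent metrics, conditional-binomial for the relative volumes
(given the non-emphysema denominator count), and a delta-method ratio
variance for E/I MLA treating the phases as independent — conservative,
since the phases share draws and the positive covariance only shrinks the
true error. Measured-vs-expected checks use 3 of these SDs.

## The cohort generator

Per subject, Insp₋₉₅₀ is lognormal with natural-scale mean 6.2% and SD
9.7% (right-skewed: most smokers have little emphysema), clipped to
[0, 100]. Each gas-trapping measure is a unit-variance composite
λ·z(Insp₋₉₅₀) + γ·(latent small-airway factor) + τ·noise rescaled to its
cohort mean/SD, with λ = 0.83 / 0.51 / 0.37 for Exp₋₈₅₆ / E/I MLA / RVC —
so the emphysema-correlation ordering of the three measures is built in —
and γ chosen to give the observed cross-correlations among the measures.
Smoking status is Bernoulli (52.4% current). Metrics are clipped to
physiological ranges with clip events counted in the ground-truth record.

Outcomes follow linear equations in the *final* (post-clip) standardized
predictors: outcome = β₀ + β_e·z(Insp₋₉₅₀) + β_g·z(gas measure) + N(0, σ²),
with the default FEV₁ equation (β₀ = 2.2 L, β_e = −0.31, β_g = −0.30,
σ = 0.364) giving R² ≈ 0.68, and analogous defaults for FEV₁/FVC,
FEF₂₅₋₇₅, 6MWD (feet), SGRQ, FEV₁ and FVC % predicted, MMRC and
exacerbation frequency. Continuous spirometry/exercise outcomes are left
unclamped: clamping them would bend the linear model exactly in the
high-leverage emphysema tail and bias coefficient recovery, which is the
property the generator exists to certify. Only hard-bounded instruments are
clamped (SGRQ to [0, 100], MMRC to [0, 4] with integer rounding,
exacerbations to ≥ 0), which makes those three mildly non-linear near their
bounds. Duplicate-scan visits add standardized-scale noise ν per measure
(0.78 / 1.10 / 1.55), giving population test–retest correlations
1/√(1+ν²) ≈ 0.79 / 0.67 / 0.54; at the default 18 pairs the sample Spearman
scatters widely around these values.

**What the generator does not emulate.** Anatomical lung texture, airway
trees, reconstruction-kernel noise, scanner drift, site effects, covariate
confounding (outcome equations contain only the two CT predictors, so
generated outcome SDs are smaller than real-cohort SDs at the same R²), and
any non-linearity between CT measures and outcomes. Passing tests certify
the *measurement and statistical machinery* — thresholding, volume
arithmetic, regression contracts — on data whose truth is known; they say
nothing about segmentation quality or biological validity on real scans.

## Numerical and design choices

* Deterministic generation: every generator consumes one
  `numpy.random.default_rng(seed)`; no global random state. Identical seeds
  give bit-identical volumes and CSV bytes.
* Problem sizes: test phantoms use 10³–64³ grids and cohorts of 50–8517
  subjects — large enough that binomial Monte-Carlo error is a fraction of
  the tolerances being checked, small enough to keep the suite fast.
* Collinearity is detected by an explicit design-matrix rank check before
  fitting, and the error names the (near-)duplicated columns.
* Correlation tables degrade cell-wise: a constant column yields a NaN cell
  with a recorded reason rather than aborting the table.
* The batch pipeline excludes subjects whose scans are missing or
  unreadable, logs each exclusion, and reports analyzed + excluded =
  manifest rows.

## Known limitations

* No airway-wall morphometry (e.g. Pi10-style measures), lobe-level
  metrics, or voxel-matched parametric-response mapping; the paired
  measures here are whole-lung histogram summaries.
* Lung segmentation is an input, not a product, of the pipeline.
* The E/I MLA expectation uses the ratio-of-means approximation; the exact
  expectation of the means' ratio differs at O(1/n), far below the
  Monte-Carlo tolerance at the voxel counts used.
* GOLD staging implements the fixed-ratio rule only; lower-limit-of-normal
  variants are out of scope.
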