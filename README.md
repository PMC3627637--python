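# lungqct

Quantitative analysis of **paired inspiratory–expiratory chest CT scans** for
separating the two mechanisms of gas trapping in smokers: emphysematous
destruction of the parenchyma versus obstruction of the small airways
(< 2 mm, below CT resolution). Expiratory imaging alone cannot tell the two
apart — an emphysematous lung and an airway-obstructed lung can look equally
lucent on exhalation — so the package implements the measures that combine
both breath-hold phases, plus the cohort statistics used to compare them
against lung function, exercise capacity and quality of life.

Intended users: imaging researchers running density-mask analyses over CT
cohorts, and methods developers who need a fully synthetic, ground-truthed
test bed for such pipelines.

## Measures

With the segmented lung voxels of each phase (attenuation in Hounsfield
units), the package computes:

| Measure | Definition |
|---|---|
| Insp₋₉₅₀ | % of inspiratory lung voxels with HU < −950 (emphysema index) |
| Exp₋₈₅₆ | % of expiratory lung voxels with HU < −856 (percent gas trapping) |
| E/I MLA | ratio of expiratory to inspiratory mean lung attenuation |
| RVC₈₅₆₋₉₅₀ | expiratory − inspiratory relative lung volume, where relative volume = (voxels with −950 ≤ HU < −856) / (voxels with HU ≥ −950) |
| Residuals | per-subject residuals of the cohort OLS of Exp₋₈₅₆ on Insp₋₉₅₀ — orthogonal to emphysema by construction |
| TLC, FRC | CT lung volumes (voxel count × voxel volume) at full inspiration / end-tidal expiration |

Emphysema is classed *absent* below Insp₋₉₅₀ = 5% (ex-smokers) / 4%
(current smokers) and *severe* above 15% / 14%; current smokers get lower
cut-points because smoking raises lung density. Cohort statistics cover
Pearson/Spearman correlation tables, emphysema-severity stratification,
GOLD spirometric staging, duplicate-scan reproducibility, and standardized
joint regressions

&nbsp;&nbsp;&nbsp;&nbsp;outcome = β₀ + β₁·z(Insp₋₉₅₀) + β₂·z(gas-trapping measure) + ε,

where z(·) standardizes to mean 0, SD 1, so each β is the outcome change
per one standard deviation and the model R² measures explanatory power.

The statistical pieces follow the statsmodels idiom: build a model object,
call `fit()`, read a results object (`GasTrappingResidualModel` →
`ResidualFitResults`, `JointOutcomeModel` → `JointModelResults`), each with
a `summary()`.

## Worked example

Generate a three-compartment phantom (25% emphysema, 20% air-trapped, rest
normal parenchyma), measure it, and compare against the phantom's
closed-form truncated-normal expectations:

```python
import lungqct as L

spec = L.PhantomSpec(shape=(64, 64, 64), f_emph=0.25, f_trap=0.20, seed=7)
pair, truth = L.generate_phantom_pair(spec)
m = L.compute_scan_pair_metrics(pair)
```

```
Insp-950  measured  24.93 %   expected  24.95 %
Exp-856   measured  40.06 %   expected  40.16 %
E/I MLA   measured 0.9050     expected 0.9049
RVC       measured -0.5543    expected -0.5537
TLC 0.1000 L, FRC 0.0649 L, FRC/TLC 0.649
emphysema: severe
```

The measured emphysema index matches the programmed 25% compartment (the
other compartments contribute < 0.1% below −950 HU), and the pair is
classed severe. On a synthetic 5000-subject cohort, the residualization and
a joint outcome model:

```python
df, dups, truth = L.generate_cohort(L.CohortSpec(n=5000, seed=7))
fit = L.fit_gas_trapping_residuals(df["exp_856"], df["insp_950"])
print(fit.summary())
print(L.joint_outcome_model(df, "fev1_l", "ei_mla").summary())
```

```
Gas-trapping residualization: Exp-856 ~ Insp-950 (OLS)
  n = 5000 complete subjects (0 excluded for missing data)
  intercept = 12.1590 %
  slope     = 1.6383 % per %
  R^2       = 0.6221
  residual SD = 10.8978 %

Joint model: fev1_l ~ z(insp_950) + z(ei_mla)
  n = 5000
  beta emphysema    = -0.3065 per SD (p = 0)
  beta gas trapping = -0.3055 per SD (p = 0)
  R^2 = 0.6777
```

The fitted betas recover the generator's programmed effects (−0.31 and
−0.30 L of FEV₁ per SD) and the model explains 68% of the outcome variance.

### Command line

```sh
lungqct simulate cohort --n 100 --seed 7 --out cohort/      # synthetic tables
lungqct simulate phantom --shape 32 --seed 3 --out phantom/ # NIfTI pair + truth
lungqct cohort --manifest phantom/phantom_manifest.csv --out results/
lungqct metrics --insp-volume v.nii.gz --insp-mask m.nii.gz \
                --exp-volume v.nii.gz --exp-mask m.nii.gz
```

Batch runs are manifest-driven (CSV mapping `subject_id` to the four NIfTI
paths and smoking status, optionally joined with a clinical CSV); outputs
are per-subject metrics, residual-fit JSON, stratified correlation tables,
joint-model tables and a Markdown report. Subjects with unreadable scans
are excluded and counted.

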