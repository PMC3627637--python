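"""Synthetic phantoms and cohorts with known ground truth.

Two generators make the whole pipeline testable without any scan archive:

**Phantom scan pairs.** The lung is a filled ellipsoid whose voxels are an
i.i.d. mixture of three tissue compartments — emphysema, air-trapped, and
normal parenchyma — each drawing inspiratory HU from a normal truncated to
the CT range [-1024, 100]. Expiration retains a random fraction of the lung
voxels (end-tidal volumes are smaller) and shifts each compartment's HU by
a fixed amount: emphysematous lung barely densifies (destroyed parenchyma
cannot empty), trapped lung stays lucent (its airways close), and normal
lung densifies strongly. Because the compartments are truncated normals and
the expiratory values are the inspiratory draws plus a shift, every density
metric has a closed-form expectation (:func:`expected_phantom_metrics`),
which serves as an independent oracle for the measurement code.

**Subject cohorts.** Per-subject CT metrics are built from a right-skewed
emphysema index plus a latent small-airway severity factor, with loadings
chosen so the measure-vs-emphysema correlation ordering seen in large
smoker cohorts (Exp-856 strongest, then E/I MLA, then RVC) emerges by
construction. Clinical outcomes follow linear equations in the two
standardized CT predictors plus Gaussian noise, so regression code can be
checked against known coefficients. Duplicate-scan pairs with test-retest
noise support reproducibility analyses.

All randomness flows from the explicit ``seed`` in each spec; the same seed
reproduces bit-identical volumes and tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import (
    EMPHYSEMA_THRESHOLD_HU,
    GAS_TRAPPING_THRESHOLD_HU,
    classify_emphysema_severity,
)
from .errors import ValidationError
from .volumes import AttenuationVolume, LungSegmentation, ScanPair, SmokingStatus

logger = logging.getLogger(__name__)

HU_TRUNC_LO = -1024.0
HU_TRUNC_HI = 100.0

COMPARTMENTS = ("emphysema", "trapped", "normal")


# ---------------------------------------------------------------------------
# phantom scan pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a three-compartment lung phantom.

    Defaults place emphysema almost entirely below -950 HU in both phases,
    keep trapped lung inside the -950..-856 band on expiration, and push
    normal lung above -856 on expiration (+150 HU densification) — the
    configuration in which expiratory lucency alone cannot tell the two
    gas-trapping mechanisms apart.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    f_emph: float = 0.1
    f_trap: float = 0.2
    insp_means: tuple[float, float, float] = (-990.0, -880.0, -870.0)  # HU
    insp_sds: tuple[float, float, float] = (15.0, 20.0, 25.0)          # HU
    exp_shifts: tuple[float, float, float] = (5.0, 10.0, 150.0)        # HU
    exp_volume_scale: float = 0.65
    smoking_status: SmokingStatus = SmokingStatus.FORMER
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValidationError(f"shape must be 3 positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if not (0 <= self.f_emph <= 1 and 0 <= self.f_trap <= 1):
            raise ValidationError("compartment fractions must lie in [0, 1]")
        if self.f_emph + self.f_trap > 1 + 1e-12:
            raise ValidationError(
                f"f_emph + f_trap = {self.f_emph + self.f_trap:.3f} exceeds 1"
            )
        if any(sd <= 0 for sd in self.insp_sds):
            raise ValidationError("compartment SDs must be strictly positive")
        if not 0 < self.exp_volume_scale <= 1:
            raise ValidationError("exp_volume_scale must be in (0, 1]")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.f_emph, self.f_trap, 1.0 - self.f_emph - self.f_trap)

    def to_json(self) -> str:
        d = asdict(self)
        d["smoking_status"] = SmokingStatus(self.smoking_status).value
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        for key in ("shape", "spacing", "insp_means", "insp_sds", "exp_shifts"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _truncnorm(mean: float, sd: float) -> stats.rv_continuous:
    a = (HU_TRUNC_LO - mean) / sd
    b = (HU_TRUNC_HI - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _compartment_dists(spec: PhantomSpec):
    return [_truncnorm(m, s) for m, s in zip(spec.insp_means, spec.insp_sds)]


@dataclass
class ExpectedMetrics:
    """Closed-form expected densitometry for a phantom spec."""

    insp_950: float
    exp_856: float
    ei_mla: float
    rvc_856_950: float
    tlc_l: float
    frc_l: float
    frc_tlc: float


@dataclass
class PhantomTruth:
    """Realized compartment counts plus closed-form expectations and their
    Monte-Carlo standard errors at the realized sample sizes."""

    insp_counts: dict
    exp_counts: dict
    n_insp: int
    n_exp: int
    expected: ExpectedMetrics
    standard_errors: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "insp_counts": self.insp_counts,
                "exp_counts": self.exp_counts,
                "n_insp": self.n_insp,
                "n_exp": self.n_exp,
                "expected": asdict(self.expected),
                "standard_errors": self.standard_errors,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Filled ellipsoid with semi-axes at 45% of each grid dimension."""
    coords = np.indices(shape, dtype=float)
    centers = [(s - 1) / 2.0 for s in shape]
    semi = [max(0.45 * s, 0.5) for s in shape]
    r2 = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, centers, semi))
    return r2 <= 1.0


def expected_phantom_metrics(spec: PhantomSpec) -> ExpectedMetrics:
    """Expectations of every density metric under the phantom's mixture model.

    Tail probabilities come from the truncated-normal CDFs; the expiratory
    distribution of compartment *c* is the inspiratory one shifted by its
    densification, so P(exp HU < t) = F_c(t - shift_c). The E/I MLA
    expectation is the ratio of the expected compartment-weighted means
    (first-order; the Monte-Carlo error of the ratio is handled separately).
    """
    dists = _compartment_dists(spec)
    f = np.asarray(spec.fractions)
    shifts = np.asarray(spec.exp_shifts)

    p_insp_950 = np.array([d.cdf(EMPHYSEMA_THRESHOLD_HU) for d in dists])
    p_exp_856 = np.array(
        [d.cdf(GAS_TRAPPING_THRESHOLD_HU - s) for d, s in zip(dists, shifts)]
    )
    insp_950 = 100.0 * float(f @ p_insp_950)
    exp_856 = 100.0 * float(f @ p_exp_856)

    means = np.array([d.mean() for d in dists])
    mla_insp = float(f @ means)
    mla_exp = float(f @ (means + shifts))
    ei = mla_exp / mla_insp

    def _relative(thresh_lo, thresh_hi, shift):
        # fraction of non-emphysematous lung inside the band, per phase
        p_below_lo = np.array([d.cdf(thresh_lo - s) for d, s in zip(dists, shift)])
        p_below_hi = np.array([d.cdf(thresh_hi - s) for d, s in zip(dists, shift)])
        p_band = float(f @ (p_below_hi - p_below_lo))
        p_denom = float(f @ (1.0 - p_below_lo))
        return p_band / p_denom if p_denom > 0 else np.nan, p_band, p_denom

    rel_insp, _, _ = _relative(
        EMPHYSEMA_THRESHOLD_HU, GAS_TRAPPING_THRESHOLD_HU, np.zeros(3)
    )
    rel_exp, _, _ = _relative(EMPHYSEMA_THRESHOLD_HU, GAS_TRAPPING_THRESHOLD_HU, shifts)
    rvc = rel_exp - rel_insp

    n_lung = int(ellipsoid_mask(tuple(int(s) for s in spec.shape)).sum())
    voxel_l = float(np.prod(spec.spacing)) * 1e-6
    tlc = n_lung * voxel_l
    frc = tlc * spec.exp_volume_scale  # expected retained fraction

    return ExpectedMetrics(
        insp_950=insp_950,
        exp_856=exp_856,
        ei_mla=ei,
        rvc_856_950=rvc,
        tlc_l=tlc,
        frc_l=frc,
        frc_tlc=spec.exp_volume_scale,
    )


def _phantom_standard_errors(spec: PhantomSpec, n_insp: int, n_exp: int) -> dict:
    """Monte-Carlo standard errors of the measured metrics about their
    expectations, at the realized voxel counts.

    Percent metrics are binomial; the relative volumes are conditional
    binomials within the non-emphysema denominator; the E/I MLA error adds
    the two phase-mean delta-method terms in quadrature (conservative: the
    phases share draws, and the shared-draw covariance only shrinks the
    true error).
    """
    dists = _compartment_dists(spec)
    f = np.asarray(spec.fractions)
    shifts = np.asarray(spec.exp_shifts)

    def binom_se(p, n):
        return 100.0 * np.sqrt(max(p * (1 - p), 0.0) / n)

    p950 = float(f @ np.array([d.cdf(EMPHYSEMA_THRESHOLD_HU) for d in dists]))
    p856 = float(
        f @ np.array([d.cdf(GAS_TRAPPING_THRESHOLD_HU - s) for d, s in zip(dists, shifts)])
    )

    means = np.array([d.mean() for d in dists])
    variances = np.array([d.var() for d in dists])

    def mixture_var(mu_shift):
        m = means + mu_shift
        grand = float(f @ m)
        return float(f @ (variances + m**2)) - grand**2, grand

    v_i, m_i = mixture_var(np.zeros(3))
    v_e, m_e = mixture_var(shifts)
    ratio = m_e / m_i
    se_ei = abs(ratio) * np.sqrt(v_e / (n_exp * m_e**2) + v_i / (n_insp * m_i**2))

    def rel_se(shift, n):
        p_lo = np.array([d.cdf(EMPHYSEMA_THRESHOLD_HU - s) for d, s in zip(dists, shift)])
        p_hi = np.array(
            [d.cdf(GAS_TRAPPING_THRESHOLD_HU - s) for d, s in zip(dists, shift)]
        )
        p_band = float(f @ (p_hi - p_lo))
        p_denom = float(f @ (1.0 - p_lo))
        if p_denom <= 0:
            return np.inf
        q = p_band / p_denom
        return np.sqrt(max(q * (1 - q), 0.0) / (n * p_denom))

    se_rvc = np.sqrt(rel_se(np.zeros(3), n_insp) ** 2 + rel_se(shifts, n_exp) ** 2)

    return {
        "insp_950": binom_se(p950, n_insp),
        "exp_856": binom_se(p856, n_exp),
        "ei_mla": float(se_ei),
        "rvc_856_950": float(se_rvc),
    }


def generate_phantom_pair(spec: PhantomSpec) -> tuple[ScanPair, PhantomTruth]:
    """Realize one phantom inspiratory/expiratory pair plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    mask = ellipsoid_mask(shape)
    n = int(mask.sum())

    labels = rng.choice(3, size=n, p=list(spec.fractions))
    hu = np.empty(n)
    dists = _compartment_dists(spec)
    for c, dist in enumerate(dists):
        idx = labels == c
        if idx.any():
            hu[idx] = dist.rvs(size=int(idx.sum()), random_state=rng)

    background = 0.0  # soft tissue outside the lung
    insp_grid = np.full(shape, background)
    insp_grid[mask] = hu

    keep = rng.random(n) < spec.exp_volume_scale
    exp_mask = np.zeros(shape, dtype=bool)
    lung_idx = np.argwhere(mask)
    kept_idx = lung_idx[keep]
    exp_mask[tuple(kept_idx.T)] = True
    shifts = np.asarray(spec.exp_shifts)
    exp_grid = np.full(shape, background)
    exp_grid[tuple(kept_idx.T)] = hu[keep] + shifts[labels[keep]]

    pair = ScanPair(
        insp_volume=AttenuationVolume(insp_grid, spec.spacing),
        insp_mask=LungSegmentation(mask),
        exp_volume=AttenuationVolume(exp_grid, spec.spacing),
        exp_mask=LungSegmentation(exp_mask),
        smoking_status=spec.smoking_status,
    )
    n_exp = int(keep.sum())
    truth = PhantomTruth(
        insp_counts={c: int((labels == i).sum()) for i, c in enumerate(COMPARTMENTS)},
        exp_counts={c: int(((labels == i) & keep).sum()) for i, c in enumerate(COMPARTMENTS)},
        n_insp=n,
        n_exp=n_exp,
        expected=expected_phantom_metrics(spec),
        standard_errors=_phantom_standard_errors(spec, n, max(n_exp, 1)),
    )
    return pair, truth


# ---------------------------------------------------------------------------
# subject cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeEquation:
    """Linear generating equation: outcome = intercept + b_e*z(emph) + b_g*z(gas) + noise."""

    intercept: float
    beta_emphysema: float
    beta_gastrap: float
    noise_sd: float
    gas_measure: str = "ei_mla"
    clip: tuple[float, float] | None = None
    integer: bool = False


def _default_outcomes() -> dict[str, OutcomeEquation]:
    # Betas (outcome units per 1 SD) and noise SDs set so the two-predictor
    # models attain the reference R^2 values; intercepts are cohort means.
    # Continuous spirometry/exercise outcomes are pure linear-Gaussian (no
    # clamp), so regression code can recover the betas exactly; only
    # hard-bounded instruments are clamped, which makes them mildly
    # non-linear in the tails.
    return {
        "fev1_l": OutcomeEquation(2.2, -0.31, -0.30, 0.364),
        "fev1_fvc": OutcomeEquation(0.67, -0.09, -0.06, 0.086),
        "fef2575": OutcomeEquation(1.75, -0.29, -0.51, 0.676),
        "sixmwd": OutcomeEquation(1363.0, -46.3, -22.0, 68.3),
        "sgrq_total": OutcomeEquation(27.0, 2.8, 1.9, 4.83, clip=(0.0, 100.0)),
        "fev1_pct_pred": OutcomeEquation(76.6, -8.0, -7.5, 12.0),
        "fvc_pct_pred": OutcomeEquation(87.2, -3.0, -4.0, 12.0),
        "mmrc": OutcomeEquation(1.3, 0.30, 0.30, 0.9, clip=(0.0, 4.0), integer=True),
        "exacerbation_freq": OutcomeEquation(0.4, 0.15, 0.10, 0.6, clip=(0.0, 12.0)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic smoker cohort.

    The emphysema index is lognormal (right-skewed, cohort mean ~6%, SD
    ~10%). Each gas-trapping measure is a unit-variance composite
    lambda*z(emphysema) + gamma*latent small-airway factor + tau*noise,
    rescaled to its cohort mean/SD; the lambdas set the measure-vs-emphysema
    correlations and decrease from Exp-856 to E/I MLA to RVC.
    """

    n: int = 1000
    seed: int = 0
    # lognormal underlying mu/sigma for insp_950 (mean 6.2, SD 9.7 on the natural scale)
    insp950_log_mu: float = 1.2055
    insp950_log_sigma: float = 1.1128
    current_smoker_fraction: float = 0.524
    # (lambda on z-emphysema, gamma on latent factor, target mean, target SD)
    loadings: dict = field(
        default_factory=lambda: {
            "exp_856": (0.83, 0.50, 21.9, 19.9),
            "ei_mla": (0.51, 0.74, 0.87, 0.07),
            "rvc_856_950": (0.37, 0.53, -0.37, 0.18),
            "frc_tlc": (0.50, 0.78, 0.58, 0.13),
        }
    )
    outcomes: dict = field(default_factory=_default_outcomes)
    n_duplicates: int = 18
    # test-retest noise SD on the standardized scale, per measure
    retest_noise_sd: dict = field(
        default_factory=lambda: {"exp_856": 0.78, "ei_mla": 1.10, "rvc_856_950": 1.55}
    )

    def __post_init__(self):
        if self.n < 10:
            raise ValidationError(f"cohort n must be >= 10, got {self.n}")
        if any(eq.noise_sd < 0 for eq in self.outcomes.values()):
            raise ValidationError("outcome noise SDs must be non-negative")
        for name, (lam, gam, _, sd) in self.loadings.items():
            if lam**2 + gam**2 > 1 + 1e-9:
                raise ValidationError(f"loadings for {name} exceed unit variance")
            if sd <= 0:
                raise ValidationError(f"target SD for {name} must be positive")
        if not 0 <= self.current_smoker_fraction <= 1:
            raise ValidationError("current_smoker_fraction must be in [0, 1]")
        if self.n_duplicates > self.n:
            raise ValidationError("cannot have more duplicate pairs than subjects")


@dataclass
class CohortTruth:
    """Generator ground truth: loadings, outcome equations, bookkeeping."""

    loadings: dict
    outcomes: dict
    clamp_events: dict
    retest_noise_sd: dict
    seed: int

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "loadings": self.loadings,
                "outcomes": {k: asdict(v) for k, v in self.outcomes.items()},
                "clamp_events": self.clamp_events,
                "retest_noise_sd": self.retest_noise_sd,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


METRIC_RANGES = {
    "exp_856": (0.0, 100.0),
    "ei_mla": (0.4, 1.15),
    "rvc_856_950": (-1.0, 1.0),
    "frc_tlc": (0.1, 1.1),
}


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate a subject table, duplicate-scan table, and ground truth.

    Returns ``(subjects, duplicates, truth)``. ``subjects`` has one row per
    subject with CT metrics, clinical outcomes and covariates; ``duplicates``
    has two visits for the first ``n_duplicates`` subjects.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    insp_950 = np.exp(rng.normal(spec.insp950_log_mu, spec.insp950_log_sigma, n))
    clamp_events = {"insp_950": int((insp_950 > 100).sum())}
    insp_950 = np.clip(insp_950, 0.0, 100.0)

    z_emph = (insp_950 - insp_950.mean()) / insp_950.std(ddof=1)
    latent = rng.normal(size=n)  # small-airway severity factor

    metrics: dict[str, np.ndarray] = {"insp_950": insp_950}
    for name, (lam, gam, mean, sd) in spec.loadings.items():
        tau = np.sqrt(max(1.0 - lam**2 - gam**2, 0.0))
        z = lam * z_emph + gam * latent + tau * rng.normal(size=n)
        raw = mean + sd * z
        lo, hi = METRIC_RANGES[name]
        clamp_events[name] = int(((raw < lo) | (raw > hi)).sum())
        metrics[name] = np.clip(raw, lo, hi)
    if clamp_events_total := sum(clamp_events.values()):
        logger.info("generate_cohort: clamped %d values to physiological ranges",
                    clamp_events_total)

    smoking = np.where(
        rng.random(n) < spec.current_smoker_fraction,
        SmokingStatus.CURRENT.value,
        SmokingStatus.FORMER.value,
    )

    df = pd.DataFrame({"subject_id": [f"S{i:05d}" for i in range(n)], **metrics})
    df["smoking_status"] = smoking
    df["emphysema_class"] = [
        classify_emphysema_severity(v, s).value for v, s in zip(insp_950, smoking)
    ]

    # CT lung volumes consistent with frc_tlc
    tlc = np.clip(rng.normal(5.5, 1.0, n), 2.5, 9.5)
    df["tlc_l"] = tlc
    df["frc_l"] = tlc * df["frc_tlc"]

    # outcomes from the *final* (clamped) metric columns so recovery is exact
    z_cols = {}
    for name in ("insp_950", *spec.loadings):
        v = df[name].to_numpy()
        z_cols[name] = (v - v.mean()) / v.std(ddof=1)
    for out_name, eq in spec.outcomes.items():
        y = (
            eq.intercept
            + eq.beta_emphysema * z_cols["insp_950"]
            + eq.beta_gastrap * z_cols[eq.gas_measure]
            + (eq.noise_sd * rng.normal(size=n) if eq.noise_sd > 0 else 0.0)
        )
        if eq.clip is not None:
            clamp_events[out_name] = int(((y < eq.clip[0]) | (y > eq.clip[1])).sum())
            y = np.clip(y, *eq.clip)
        if eq.integer:
            y = np.round(y)
        df[out_name] = y

    # covariates
    df["age"] = np.clip(rng.normal(59.6, 9.0, n), 45, 80)
    df["pack_years"] = np.clip(rng.normal(44.3, 24.8, n), 10, 200)
    df["sex_male"] = (rng.random(n) < 0.532).astype(int)

    duplicates = _generate_duplicates(spec, df, rng)
    truth = CohortTruth(
        loadings={k: list(v) for k, v in spec.loadings.items()},
        outcomes=dict(spec.outcomes),
        clamp_events=clamp_events,
        retest_noise_sd=dict(spec.retest_noise_sd),
        seed=spec.seed,
    )
    return df, duplicates, truth


def _generate_duplicates(spec: CohortSpec, df: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Second-visit gas-trapping metrics for the first n_duplicates subjects.

    Visit-2 value = mean + SD * (z1 + nu*eps)/sqrt(1+nu^2): variance is
    preserved and the population test-retest correlation is 1/sqrt(1+nu^2).
    """
    k = spec.n_duplicates
    if k == 0:
        return pd.DataFrame(
            columns=["subject_id", "visit", "exp_856", "ei_mla", "rvc_856_950"]
        )
    sub = df.iloc[:k]
    rows = []
    for _, row in sub.iterrows():
        rows.append(
            {"subject_id": row.subject_id, "visit": 1,
             **{m: row[m] for m in spec.retest_noise_sd}}
        )
    for _, row in sub.iterrows():
        entry = {"subject_id": row.subject_id, "visit": 2}
        for m, nu in spec.retest_noise_sd.items():
            _, _, mean, sd = spec.loadings[m]
            z1 = (row[m] - mean) / sd
            z2 = (z1 + nu * rng.normal()) / np.sqrt(1 + nu**2)
            lo, hi = METRIC_RANGES[m]
            entry[m] = float(np.clip(mean + sd * z2, lo, hi))
        rows.append(entry)
    return pd.DataFrame(rows)
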