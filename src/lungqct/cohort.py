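"""Cohort-level statistics comparing CT measures with clinical outcomes.

Mirrors the analysis framework used to evaluate competing gas-trapping
measures in large smoker cohorts: Pearson correlation tables between each
measure and spirometry / exercise / symptom outcomes, standardized joint
regression models (emphysema + one gas-trapping measure per outcome, betas
per 1-SD change, model R^2), emphysema-severity stratification, GOLD
spirometric staging, and duplicate-scan Spearman reproducibility.

Conventions: sample (n-1) standard deviations for standardization;
pairwise-complete observations for correlations, listwise deletion for
regressions; two-sided p-values with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .densitometry import DensityMetrics, classify_emphysema_severity
from .errors import (
    CollinearityError,
    InsufficientDuplicatesError,
    ValidationError,
    ZeroVarianceError,
)
from .volumes import EmphysemaClass

GAS_TRAPPING_MEASURES = ("exp_856", "ei_mla", "rvc_856_950")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value."""
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero variance: a correlation input is constant")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Rank correlation (mid-ranks for ties) with two-sided p-value."""
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero variance: a correlation input is constant")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def standardize(x) -> np.ndarray:
    """Center to mean 0 and scale to sample (n-1) standard deviation 1.

    NaNs are ignored for the mean/SD and propagated through the output.
    """
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValidationError(f"need >= 2 finite values to standardize, got {finite.size}")
    sd = np.std(finite, ddof=1)
    if sd == 0:
        raise ZeroVarianceError("zero variance: cannot standardize a constant vector")
    return (x - np.mean(finite)) / sd


# ---------------------------------------------------------------------------
# joint emphysema + gas-trapping outcome models
# ---------------------------------------------------------------------------

@dataclass
class JointModelResults:
    """One fitted outcome model: betas per 1-SD predictor change, p's, R^2."""

    outcome_name: str
    gas_measure_name: str
    beta_emphysema: float
    beta_gastrap: float
    p_emphysema: float
    p_gastrap: float
    r_squared: float
    n: int
    params: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    fitted: np.ndarray
    observed: np.ndarray

    def summary(self) -> str:
        lines = [
            f"Joint model: {self.outcome_name} ~ z(insp_950) + z({self.gas_measure_name})"
            + ("" if self.params.size <= 3 else " + covariates"),
            f"  n = {self.n}",
            f"  beta emphysema    = {self.beta_emphysema:+.4g} per SD (p = {self.p_emphysema:.3g})",
            f"  beta gas trapping = {self.beta_gastrap:+.4g} per SD (p = {self.p_gastrap:.3g})",
            f"  R^2 = {self.r_squared:.4f}",
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "gas_measure": self.gas_measure_name,
            "beta_emphysema": self.beta_emphysema,
            "p_emphysema": self.p_emphysema,
            "beta_gastrap": self.beta_gastrap,
            "p_gastrap": self.p_gastrap,
            "r_squared": self.r_squared,
            "n": self.n,
        }


class JointOutcomeModel:
    """OLS of a clinical outcome on standardized emphysema + gas-trapping.

    Both CT predictors (and any numeric covariates) are standardized to
    mean 0, SD 1 on the analysis sample, so coefficients read as outcome
    units per one-SD change. Listwise deletion over the involved columns.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, gas_measure: str,
                 emphysema: str = "insp_950",
                 covariates: Sequence[str] | None = None):
        covariates = list(covariates or [])
        cols = [outcome, emphysema, gas_measure, *covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValidationError(f"columns not in data: {missing}")
        frame = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
        if len(frame) <= len(cols) + 2:
            raise ValidationError(
                f"need n > predictors + 2; have n = {len(frame)} for {len(cols) - 1} predictors"
            )
        self.data = frame
        self.outcome = outcome
        self.emphysema = emphysema
        self.gas_measure = gas_measure
        self.covariates = covariates

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, gas_measure: str,
                       **kwargs) -> "JointOutcomeModel":
        return cls(data, outcome, gas_measure, **kwargs)

    def _design(self) -> pd.DataFrame:
        X = pd.DataFrame(index=self.data.index)
        X["const"] = 1.0
        X[self.emphysema] = standardize(self.data[self.emphysema].to_numpy())
        X[self.gas_measure] = standardize(self.data[self.gas_measure].to_numpy())
        for cov in self.covariates:
            v = self.data[cov].to_numpy(dtype=float)
            # binary/dummy covariates enter as-is; continuous ones standardized
            uniq = np.unique(v)
            X[cov] = v if uniq.size <= 2 else standardize(v)
        return X

    def fit(self) -> JointModelResults:
        X = self._design()
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            corr = np.corrcoef(X.to_numpy()[:, 1:], rowvar=False)
            culprits = []
            names = list(X.columns[1:])
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    if abs(corr[i, j]) > 1 - 1e-10:
                        culprits += [names[i], names[j]]
            raise CollinearityError(
                f"collinear predictors: design rank {rank} < {X.shape[1]}"
                + (f" (culprits: {sorted(set(culprits))})" if culprits else ""),
                columns=sorted(set(culprits)),
            )
        y = self.data[self.outcome].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        return JointModelResults(
            outcome_name=self.outcome,
            gas_measure_name=self.gas_measure,
            beta_emphysema=float(res.params[self.emphysema]),
            beta_gastrap=float(res.params[self.gas_measure]),
            p_emphysema=float(res.pvalues[self.emphysema]),
            p_gastrap=float(res.pvalues[self.gas_measure]),
            r_squared=float(res.rsquared),
            n=int(res.nobs),
            params=res.params,
            pvalues=res.pvalues,
            bse=res.bse,
            fitted=np.asarray(res.fittedvalues),
            observed=y,
        )


def joint_outcome_model(data: pd.DataFrame, outcome: str, gas_measure: str,
                        covariates: Sequence[str] | None = None,
                        emphysema: str = "insp_950") -> JointModelResults:
    """Fit one standardized emphysema + gas-trapping model for an outcome."""
    return JointOutcomeModel(
        data, outcome, gas_measure, emphysema=emphysema, covariates=covariates
    ).fit()


# ---------------------------------------------------------------------------
# stratification and staging
# ---------------------------------------------------------------------------

def stratify_cohort(data: pd.DataFrame,
                    class_col: str = "emphysema_class",
                    insp_col: str = "insp_950",
                    smoking_col: str = "smoking_status") -> dict[str, pd.DataFrame]:
    """Split a cohort into all / severe-emphysema / no-emphysema subsets.

    Uses an existing ``emphysema_class`` column when present, otherwise
    classifies from ``insp_950`` and ``smoking_status``. The severe,
    intermediate and absent subsets partition the cohort.
    """
    if class_col in data.columns:
        classes = data[class_col].astype(str)
    else:
        classes = pd.Series(
            [
                classify_emphysema_severity(v, s).value
                for v, s in zip(data[insp_col], data[smoking_col])
            ],
            index=data.index,
        )
    return {
        "all": data,
        "severe_emphysema": data[classes == EmphysemaClass.SEVERE.value],
        "intermediate": data[classes == EmphysemaClass.INTERMEDIATE.value],
        "no_emphysema": data[classes == EmphysemaClass.ABSENT.value],
    }


class GoldStage(str, Enum):
    GOLD0 = "GOLD0"
    GOLD1 = "GOLD1"
    GOLD2 = "GOLD2"
    GOLD3 = "GOLD3"
    GOLD4 = "GOLD4"
    UNCLASSIFIED = "unclassified"


def gold_stage(fev1_fvc: float, fev1_pct_pred: float) -> GoldStage:
    """Spirometric COPD staging by the fixed-ratio GOLD criteria.

    Obstruction (FEV1/FVC < 0.7) is staged by FEV1 % predicted:
    >= 80 stage 1, 50-79 stage 2, 30-49 stage 3, < 30 stage 4. Without
    obstruction, preserved FEV1 (>= 80%) is GOLD 0 and reduced FEV1 with a
    normal ratio is unclassified.
    """
    if not 0.0 <= fev1_fvc <= 1.2:
        raise ValidationError(f"FEV1/FVC ratio out of range [0, 1.2]: {fev1_fvc}")
    if not 0.0 <= fev1_pct_pred <= 250.0:
        raise ValidationError(f"FEV1 %predicted out of range [0, 250]: {fev1_pct_pred}")
    if fev1_fvc < 0.7:
        if fev1_pct_pred >= 80:
            return GoldStage.GOLD1
        if fev1_pct_pred >= 50:
            return GoldStage.GOLD2
        if fev1_pct_pred >= 30:
            return GoldStage.GOLD3
        return GoldStage.GOLD4
    return GoldStage.GOLD0 if fev1_pct_pred >= 80 else GoldStage.UNCLASSIFIED


# ---------------------------------------------------------------------------
# reproducibility and correlation tables
# ---------------------------------------------------------------------------

def duplicate_reproducibility(
    pairs, measures: Sequence[str] = GAS_TRAPPING_MEASURES
) -> pd.DataFrame:
    """Spearman test-retest correlation of each gas-trapping measure.

    ``pairs`` is either a list of ``(metrics_t1, metrics_t2)`` tuples of
    :class:`DensityMetrics`, or a pair of row-aligned DataFrames (one per
    time point) containing the measure columns.
    """
    if isinstance(pairs, (tuple, list)) and len(pairs) == 2 and isinstance(pairs[0], pd.DataFrame):
        t1, t2 = pairs
    else:
        pairs = list(pairs)
        t1 = pd.DataFrame([_metrics_row(a) for a, _ in pairs])
        t2 = pd.DataFrame([_metrics_row(b) for _, b in pairs])
    if len(t1) != len(t2):
        raise ValidationError("time-point tables must be row-aligned")
    if len(t1) < 3:
        raise InsufficientDuplicatesError(
            f"insufficient duplicates: need >= 3 pairs, got {len(t1)}"
        )
    rows = []
    for m in measures:
        rho, p = spearman_correlation(t1[m].to_numpy(), t2[m].to_numpy())
        rows.append({"measure": m, "spearman_rho": rho, "p_value": p, "n": len(t1)})
    return pd.DataFrame(rows).set_index("measure")


def _metrics_row(m) -> dict:
    if isinstance(m, DensityMetrics):
        return m.to_dict()
    if isinstance(m, Mapping):
        return dict(m)
    raise ValidationError(f"cannot interpret duplicate-scan record of type {type(m)!r}")


@dataclass
class CorrelationTable:
    """Measure x outcome Pearson correlations on pairwise-complete records."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    reasons: dict

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for meas in self.r.index:
            for out in self.r.columns:
                rows.append(
                    {
                        "measure": meas,
                        "outcome": out,
                        "r": self.r.loc[meas, out],
                        "p_value": self.p.loc[meas, out],
                        "n": self.n.loc[meas, out],
                        "note": self.reasons.get((meas, out), ""),
                    }
                )
        return pd.DataFrame(rows)


def correlation_matrix(data: pd.DataFrame, measures: Sequence[str],
                       outcomes: Sequence[str],
                       method: str = "pearson") -> CorrelationTable:
    """Correlate every measure with every outcome, cell by cell.

    Cells whose inputs are constant or too sparse are reported as NaN with
    the reason recorded rather than aborting the whole table.
    """
    fn = {"pearson": pearson_correlation, "spearman": spearman_correlation}[method]
    missing = [c for c in (*measures, *outcomes) if c not in data.columns]
    if missing:
        raise ValidationError(f"columns not in data: {missing}")
    r = pd.DataFrame(index=list(measures), columns=list(outcomes), dtype=float)
    p = pd.DataFrame(index=list(measures), columns=list(outcomes), dtype=float)
    n = pd.DataFrame(0, index=list(measures), columns=list(outcomes), dtype=int)
    reasons: dict = {}
    for meas in measures:
        for out in outcomes:
            x, y = _pairwise_complete(data[meas].to_numpy(dtype=float),
                                      data[out].to_numpy(dtype=float))
            n.loc[meas, out] = x.size
            try:
                r.loc[meas, out], p.loc[meas, out] = fn(x, y)
            except (ZeroVarianceError, ValidationError) as exc:
                r.loc[meas, out] = np.nan
                p.loc[meas, out] = np.nan
                reasons[(meas, out)] = str(exc)
    return CorrelationTable(r=r, p=p, n=n, reasons=reasons)
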