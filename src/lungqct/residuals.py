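"""Residualized gas trapping: regress Exp-856 on Insp-950 across a cohort.

The fourth gas-trapping measure removes the emphysema contribution from the
expiratory density mask statistically: each subject's residual from the
cohort-wide ordinary least-squares regression of Exp-856 on Insp-950 is, by
construction, uncorrelated with the emphysema index and has zero mean.

This is a cohort-level quantity — a subject's residual depends on the
regression line fitted to everyone — so it is exposed as a small
statsmodels-style model: build a :class:`GasTrappingResidualModel` from two
vectors (or a DataFrame), call :meth:`~GasTrappingResidualModel.fit`, and
read the residuals off the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateRegressionError, ValidationError


class GasTrappingResidualModel:
    """OLS of the expiratory gas-trapping percent on the emphysema percent.

    Parameters
    ----------
    exp_856 : array-like
        Response: percent of expiratory lung voxels < -856 HU, one per subject.
    insp_950 : array-like
        Predictor: percent of inspiratory lung voxels < -950 HU.

    Missing values are excluded pairwise before fitting; residuals for the
    excluded subjects are reported as NaN, never imputed.
    """

    def __init__(self, exp_856, insp_950):
        y = np.asarray(exp_856, dtype=float)
        x = np.asarray(insp_950, dtype=float)
        if y.ndim != 1 or x.ndim != 1:
            raise ValidationError("exp_856 and insp_950 must be 1-D vectors")
        if y.shape != x.shape:
            raise ValidationError(
                f"length mismatch: exp_856 has {y.size} entries, insp_950 has {x.size}"
            )
        self.endog = y
        self.exog = x
        self._complete = np.isfinite(y) & np.isfinite(x)
        n = int(self._complete.sum())
        if n < 3:
            raise ValidationError(f"need at least 3 complete pairs, got {n}")
        if np.ptp(x[self._complete]) == 0:
            raise DegenerateRegressionError(
                "degenerate regression: predictor insp_950 is constant"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, exp_col: str = "exp_856",
                       insp_col: str = "insp_950") -> "GasTrappingResidualModel":
        return cls(data[exp_col].to_numpy(), data[insp_col].to_numpy())

    def fit(self) -> "ResidualFitResults":
        keep = self._complete
        x, y = self.exog[keep], self.endog[keep]
        res = sm.OLS(y, sm.add_constant(x)).fit()
        residuals = np.full(self.endog.shape, np.nan)
        residuals[keep] = res.resid
        return ResidualFitResults(
            intercept=float(res.params[0]),
            slope=float(res.params[1]),
            residuals=residuals,
            n=int(keep.sum()),
            n_missing=int((~keep).sum()),
            r_squared=float(res.rsquared),
            model=self,
        )


@dataclass
class ResidualFitResults:
    """Fitted residualization: line coefficients plus per-subject residuals.

    ``residuals`` is aligned with the input vectors (NaN where a subject was
    excluded for missing data). The complete-case residuals have zero mean
    and zero Pearson correlation with the predictor by construction.
    """

    intercept: float
    slope: float
    residuals: np.ndarray
    n: int
    n_missing: int
    r_squared: float
    model: GasTrappingResidualModel = field(repr=False, default=None)

    @property
    def resid_complete(self) -> np.ndarray:
        return self.residuals[np.isfinite(self.residuals)]

    def predict(self, insp_950) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(insp_950, dtype=float)

    def summary(self) -> str:
        lines = [
            "Gas-trapping residualization: Exp-856 ~ Insp-950 (OLS)",
            f"  n = {self.n} complete subjects ({self.n_missing} excluded for missing data)",
            f"  intercept = {self.intercept:.4f} %",
            f"  slope     = {self.slope:.4f} % per %",
            f"  R^2       = {self.r_squared:.4f}",
            f"  residual SD = {np.std(self.resid_complete, ddof=1):.4f} %",
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "intercept": self.intercept,
                "slope": self.slope,
                "n": self.n,
                "n_missing": self.n_missing,
                "r_squared": self.r_squared,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def fit_gas_trapping_residuals(exp_856, insp_950) -> ResidualFitResults:
    """Convenience wrapper: build the model and fit in one call."""
    return GasTrappingResidualModel(exp_856, insp_950).fit()
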