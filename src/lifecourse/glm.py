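"""Maximum-likelihood logistic regression with likelihood/AIC bookkeeping.

Thin, validated wrapper around statsmodels' binomial GLM (IRLS) returning a
:class:`FitResult` that the selection and evaluation layers consume, plus
Wald odds-ratio tables in the layout epidemiological papers print.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class SeparationError(RuntimeError):
    """A column perfectly (or quasi-) separates the outcome."""


@dataclass
class FitResult:
    """A fitted logistic model: point estimates plus likelihood bookkeeping."""

    coef: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    fitted: np.ndarray | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.coef.index)

    def to_json(self, **kwargs) -> str:
        payload = {
            "terms": list(self.coef.index),
            "coef": [float(v) for v in self.coef],
            "se": [float(v) for v in self.se],
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }
        return json.dumps(payload, **kwargs)


def _validate_outcome(design: pd.DataFrame, outcome) -> np.ndarray:
    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or len(y) != len(design):
        raise ValueError("outcome must be a 1-d vector matching the design rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if len(design) <= design.shape[1]:
        raise ValueError(
            f"need more observations ({len(design)}) than parameters ({design.shape[1]})")
    return y


def _check_separation(coef: pd.Series, design: pd.DataFrame,
                      threshold: float = 15.0) -> None:
    binary = [c for c in design.columns
              if np.isin(design[c].to_numpy(), (0.0, 1.0)).all()]
    for c in binary:
        if c != "intercept" and abs(coef[c]) > threshold:
            raise SeparationError(
                f"column {c!r} appears to separate the outcome "
                f"(|coef| = {abs(coef[c]):.1f} > {threshold})")


def fit_logistic(
    design: pd.DataFrame,
    outcome,
    maxiter: int = 100,
    tol: float = 1e-8,
    weights=None,
) -> FitResult:
    """Fit a Bernoulli logistic model by IRLS.

    ``weights`` are optional frequency weights (aggregated-count data);
    ``n_obs`` then reports the weighted total.
    """
    y = _validate_outcome(design, outcome)
    x = design.to_numpy(float)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation handled explicitly below
        if weights is None:
            try:  # Newton is much faster than IRLS on these designs
                res = sm.Logit(y, x).fit(method="newton", maxiter=maxiter,
                                         tol=tol, disp=0)
                converged = bool(res.mle_retvals["converged"])
            except Exception:
                res = None
        if res is None or (weights is None and not converged):
            kwargs = {}
            if weights is not None:
                kwargs["freq_weights"] = np.asarray(weights, dtype=float)
            res = sm.GLM(y, x, family=sm.families.Binomial(), **kwargs).fit(
                maxiter=maxiter, tol=tol)
            converged = bool(res.converged)
    coef = pd.Series(np.asarray(res.params), index=design.columns)
    if not np.isfinite(coef).all():
        raise SeparationError("non-finite coefficients; data may be separated")
    _check_separation(coef, design)
    return FitResult(
        coef=coef,
        cov=pd.DataFrame(np.asarray(res.cov_params()), index=design.columns,
                         columns=design.columns),
        loglik=float(res.llf),
        n_params=design.shape[1],
        n_obs=len(y) if weights is None else int(round(float(np.sum(weights)))),
        converged=converged,
        fitted=np.asarray(res.predict(x)),
    )


@dataclass(frozen=True)
class ORRow:
    term: str
    or_: float
    ci_low: float
    ci_high: float


def odds_ratio_table(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Wald odds ratios and CIs for every non-intercept term.

    Returns a DataFrame with columns ``term, OR, ci_low, ci_high``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if not fit.converged:
        raise ValueError("odds-ratio table requested for a non-converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for term in fit.coef.index:
        if term == "intercept":
            continue
        b, se = float(fit.coef[term]), float(fit.se[term])
        rows.append(ORRow(term, float(np.exp(b)),
                          float(np.exp(b - z * se)), float(np.exp(b + z * se))))
    return pd.DataFrame([r.__dict__ for r in rows]).rename(columns={"or_": "OR"})
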