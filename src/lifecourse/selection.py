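"""Per-exposure temporal-pattern selection by likelihood-ratio trimming.

For each exposure the five restricted temporal hypotheses are tested
against the full (saturated-pattern) model while every *other* exposure is
kept at its full parameterization.  The selection rule:

1. a restricted model whose likelihood-ratio test against the full model is
   non-significant (p > 0.05) fits the data as well, and qualifies;
2. if several qualify, the one with the smallest AIC is selected;
3. if none qualifies, the full model is kept.

The final model assembles the chosen hypothesis for every exposure, is
refitted, and reported with its odds-ratio table and c-statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import (EXPOSURES, RESTRICTED_HYPOTHESES, CovariateStrategy,
                       TemporalHypothesis, build_design, hypothesis_columns)
from .evaluation import c_statistic
from .glm import FitResult, fit_logistic, odds_ratio_table
from .mixed import fit_random_intercept_logistic

OUTCOME_COLUMN = "no_graduation"

logger = logging.getLogger("lifecourse.selection")


class SelectionError(RuntimeError):
    """A component fit failed; no silent selection is made."""


@dataclass(frozen=True)
class LRTResult:
    stat: float
    df: int
    p: float


def lrt(full: FitResult, restricted: FitResult, tol: float = 1e-4) -> LRTResult:
    """Likelihood-ratio test of a nested restricted model against the full one."""
    df = full.n_params - restricted.n_params
    if df <= 0:
        raise ValueError("restricted model must have fewer parameters than the full")
    stat = 2.0 * (full.loglik - restricted.loglik)
    if stat < -tol:
        raise ValueError(
            f"restricted log-likelihood exceeds the full model's by {-stat / 2:.3g}; "
            "nesting violated or a fit failed to converge")
    stat = max(stat, 0.0)
    return LRTResult(stat=stat, df=df, p=float(stats.chi2.sf(stat, df)))


@dataclass(frozen=True)
class Candidate:
    hypothesis: TemporalHypothesis
    lrt: LRTResult
    aic: float


@dataclass
class ExposureSelection:
    exposure: str
    chosen: TemporalHypothesis
    full_aic: float
    candidates: dict[TemporalHypothesis, Candidate]


@dataclass
class SelectionTable:
    """Per-exposure chosen hypotheses plus the refitted final model."""

    strategy: CovariateStrategy
    selections: dict[str, ExposureSelection]
    final_fit: FitResult | None = None
    final_or_table: pd.DataFrame | None = None
    final_c: float = float("nan")
    p_threshold: float = 0.05
    iterations: int = 1

    @property
    def chosen(self) -> dict[str, TemporalHypothesis]:
        return {e: s.chosen for e, s in self.selections.items()}

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per exposure, the selected hypothesis flagged."""
        rows = []
        for e, s in self.selections.items():
            row = {"exposure": e, "chosen": s.chosen.value}
            for h in TemporalHypothesis:
                row[h.value] = "x" if h is s.chosen else ""
            rows.append(row)
        return pd.DataFrame(rows)

    def candidates_frame(self) -> pd.DataFrame:
        """Long-format diagnostics: LRT stat/df/p and AIC per candidate."""
        rows = []
        for e, s in self.selections.items():
            rows.append({"exposure": e, "hypothesis": TemporalHypothesis.FULL.value,
                         "lrt_stat": np.nan, "df": np.nan, "p": np.nan,
                         "aic": s.full_aic, "chosen": s.chosen is TemporalHypothesis.FULL})
            for h, c in s.candidates.items():
                rows.append({"exposure": e, "hypothesis": h.value,
                             "lrt_stat": c.lrt.stat, "df": c.lrt.df, "p": c.lrt.p,
                             "aic": c.aic, "chosen": h is s.chosen})
        return pd.DataFrame(rows)


Fitter = Callable[[pd.DataFrame, np.ndarray], FitResult]


def make_fitter(cohort: pd.DataFrame, strategy: CovariateStrategy,
                n_nodes: int = 15) -> Fitter:
    """Ordinary logistic fitter, or the family-clustered one for SIBLING."""
    if strategy is CovariateStrategy.SIBLING:
        if "family_id" not in cohort.columns:
            raise ValueError("sibling strategy requires a family_id column")
        fam = cohort["family_id"].to_numpy()

        def fit(design: pd.DataFrame, y: np.ndarray) -> FitResult:
            return fit_random_intercept_logistic(design, y, fam, n_nodes=n_nodes)

        return fit
    return fit_logistic


def _apply_rule(candidates: Mapping[TemporalHypothesis, Candidate],
                p_threshold: float) -> TemporalHypothesis:
    qualifying = [c for c in candidates.values() if c.lrt.p > p_threshold]
    if not qualifying:
        return TemporalHypothesis.FULL
    return min(qualifying, key=lambda c: c.aic).hypothesis


def _test_exposure(cohort, outcome, exposure, context, covariates, fit,
                   p_threshold, exposures, cache=None) -> ExposureSelection:
    hyps = dict(context)
    hyps[exposure] = TemporalHypothesis.FULL

    def cached_fit(hyps):
        if cache is None:
            return fit(build_design(cohort, hyps, covariates, exposures), outcome)
        key = tuple(sorted((e, h.value) for e, h in hyps.items()))
        if key not in cache:
            cache[key] = fit(build_design(cohort, hyps, covariates, exposures),
                             outcome)
        return cache[key]

    try:
        full_fit = cached_fit(hyps)
        if not full_fit.converged:
            raise SelectionError(f"full model for {exposure!r} did not converge")
        logger.info("fit exposure=%s hypothesis=full loglik=%.4f aic=%.4f df=%d",
                    exposure, full_fit.loglik, full_fit.aic, full_fit.n_params)
        candidates: dict[TemporalHypothesis, Candidate] = {}
        for h in RESTRICTED_HYPOTHESES:
            hyps[exposure] = h
            res = cached_fit(hyps)
            if not res.converged:
                raise SelectionError(
                    f"{h.value} model for {exposure!r} did not converge")
            test = lrt(full_fit, res)
            logger.info("fit exposure=%s hypothesis=%s loglik=%.4f aic=%.4f "
                        "df=%d lrt_p=%.4g", exposure, h.value, res.loglik,
                        res.aic, res.n_params, test.p)
            candidates[h] = Candidate(h, test, res.aic)
    except SelectionError:
        raise
    except Exception as exc:  # propagate with the exposure named
        raise SelectionError(f"selection for {exposure!r} failed: {exc}") from exc
    return ExposureSelection(exposure, _apply_rule(candidates, p_threshold),
                             full_fit.aic, candidates)


def select_for_exposure(
    cohort: pd.DataFrame,
    exposure: str,
    strategy: CovariateStrategy | str = CovariateStrategy.ALL,
    p_threshold: float = 0.05,
    exposures: Sequence[str] = EXPOSURES,
    fit: Fitter | None = None,
) -> ExposureSelection:
    """Choose the temporal hypothesis for one exposure, others held at FULL."""
    strategy = CovariateStrategy(strategy)
    fit = fit or make_fitter(cohort, strategy)
    outcome = cohort[OUTCOME_COLUMN].to_numpy(float)
    context = {e: TemporalHypothesis.FULL for e in exposures}
    return _test_exposure(cohort, outcome, exposure, context,
                          strategy.covariates, fit, p_threshold, exposures)


def select_all(
    cohort: pd.DataFrame,
    strategy: CovariateStrategy | str = CovariateStrategy.ALL,
    p_threshold: float = 0.05,
    iterative: bool = False,
    max_rounds: int = 5,
    exposures: Sequence[str] = EXPOSURES,
    fit: Fitter | None = None,
) -> SelectionTable:
    """Run the trimming procedure for every exposure and refit the final model.

    With ``iterative=False`` (default) each exposure is tested once against
    the model holding all other exposures at FULL, and the final model
    simply assembles the winners.  With ``iterative=True`` the procedure is
    repeated with the other exposures held at their currently chosen
    patterns until the selection stabilises.
    """
    strategy = CovariateStrategy(strategy)
    fit = fit or make_fitter(cohort, strategy)
    outcome = cohort[OUTCOME_COLUMN].to_numpy(float)

    context = {e: TemporalHypothesis.FULL for e in exposures}
    selections: dict[str, ExposureSelection] = {}
    cache: dict = {}  # the all-FULL reference fit recurs for every exposure
    rounds = 0
    while True:
        rounds += 1
        for e in exposures:
            selections[e] = _test_exposure(cohort, outcome, e, context,
                                           strategy.covariates, fit,
                                           p_threshold, exposures, cache=cache)
        new_context = {e: selections[e].chosen for e in exposures}
        if not iterative or new_context == context or rounds >= max_rounds:
            break
        context = new_context

    final_design = build_design(
        cohort, {e: selections[e].chosen for e in exposures},
        strategy.covariates, exposures)
    final_fit = fit(final_design, outcome)
    table = SelectionTable(strategy=strategy, selections=selections,
                           final_fit=final_fit,
                           final_or_table=odds_ratio_table(final_fit),
                           p_threshold=p_threshold, iterations=rounds)
    if final_fit.fitted is not None:
        table.final_c = c_statistic(final_fit.fitted, outcome).c
    return table
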