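"""Design-matrix construction for multi-period binary exposure trajectories.

Each exposure is observed as three binary flags, one per developmental
window (ages 0-3, 4-8, 9-13).  Six temporal hypotheses describe how such a
trajectory may act on a binary outcome:

* ``FULL`` -- one coefficient per non-reference pattern (seven dummies
  ``s100 .. s111``; the never-exposed pattern ``000`` is the reference);
* ``ACCUMULATION`` -- a single coefficient on the number of exposed periods;
* ``SENSITIVE`` -- one coefficient per period on the marginal period
  indicators (risk accumulates, but each window has its own magnitude);
* ``CRITICAL_P1`` / ``CRITICAL_P2`` / ``CRITICAL_P3`` -- a single
  coefficient on one period's marginal indicator.

All restricted encodings are exact linear functions of the seven full-model
dummies, so every restricted model is nested in the full model and
likelihood-ratio tests against it carry ``7 - n_params`` degrees of freedom.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr

#: canonical exposure names in the cohort schema
EXPOSURES = ("low_income", "mobility", "family_change", "ext_mental", "injury")

#: time-invariant covariates in the cohort schema, in reporting order
INVARIANT_COVARIATES = (
    "mother_age_first_birth",
    "family_size",
    "birth_order",
    "rural",
    "mother_unmarried",
    "male",
    "bw_low",
    "bw_high",
    "birth_year",
    "low_grade9",
)

#: covariates measured at (or before) birth — drops the grade-9 index
BIRTH_COVARIATES = tuple(c for c in INVARIANT_COVARIATES if c != "low_grade9")

#: the seven non-reference patterns, ordered as in the full-model equation
FULL_PATTERNS = ("100", "010", "001", "110", "101", "011", "111")


class CovariateStrategy(str, enum.Enum):
    """Which time-invariant covariates enter the adjustment set."""

    ALL = "all"
    BIRTH_ONLY = "birth_only"
    NONE = "none"
    SIBLING = "sibling"  # same covariates as ALL, family-clustered fit

    @property
    def covariates(self) -> tuple[str, ...]:
        if self in (CovariateStrategy.ALL, CovariateStrategy.SIBLING):
            return INVARIANT_COVARIATES
        if self is CovariateStrategy.BIRTH_ONLY:
            return BIRTH_COVARIATES
        return ()


class TemporalHypothesis(str, enum.Enum):
    """One of the six candidate temporal models for a single exposure."""

    FULL = "full"
    ACCUMULATION = "accumulation"
    SENSITIVE = "sensitive"
    CRITICAL_P1 = "critical_p1"
    CRITICAL_P2 = "critical_p2"
    CRITICAL_P3 = "critical_p3"

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self]

    @property
    def is_restricted(self) -> bool:
        return self is not TemporalHypothesis.FULL


_N_PARAMS = {
    TemporalHypothesis.FULL: 7,
    TemporalHypothesis.ACCUMULATION: 1,
    TemporalHypothesis.SENSITIVE: 3,
    TemporalHypothesis.CRITICAL_P1: 1,
    TemporalHypothesis.CRITICAL_P2: 1,
    TemporalHypothesis.CRITICAL_P3: 1,
}

RESTRICTED_HYPOTHESES = tuple(h for h in TemporalHypothesis if h.is_restricted)


@dataclass(frozen=True)
class ExposureTrajectory:
    """Three ordered binary period flags for one exposure on one person."""

    p1: int
    p2: int
    p3: int

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"trajectory flag {name} must be 0 or 1, got {v!r}")

    @property
    def pattern_code(self) -> int:
        """Integer 0..7; bijective with (p1, p2, p3)."""
        return 4 * self.p1 + 2 * self.p2 + self.p3

    @property
    def pattern(self) -> str:
        return f"{self.p1}{self.p2}{self.p3}"


def encode_full(traj: ExposureTrajectory) -> dict[str, int]:
    """One-hot pattern dummies ``s100 .. s111``; pattern 000 is all zeros."""
    return {f"s{p}": int(traj.pattern == p) for p in FULL_PATTERNS}


def encode_accumulation(traj: ExposureTrajectory) -> int:
    """Number of exposed periods (0..3)."""
    return traj.p1 + traj.p2 + traj.p3


def encode_sensitive(traj: ExposureTrajectory) -> tuple[int, int, int]:
    """Marginal period indicators: exposed in period i, whatever the others."""
    return (traj.p1, traj.p2, traj.p3)


def encode_critical(traj: ExposureTrajectory, period: int) -> int:
    """Marginal indicator for one developmental window (period 1, 2 or 3)."""
    if period not in (1, 2, 3):
        raise ValueError(f"period must be 1, 2 or 3, got {period!r}")
    return getattr(traj, f"p{period}")


def hypothesis_columns(exposure: str, hypothesis: TemporalHypothesis) -> list[str]:
    """Stable design-column names contributed by one exposure under one hypothesis."""
    h = TemporalHypothesis(hypothesis)
    if h is TemporalHypothesis.FULL:
        return [f"{exposure}_s{p}" for p in FULL_PATTERNS]
    if h is TemporalHypothesis.ACCUMULATION:
        return [f"{exposure}_nperiods"]
    if h is TemporalHypothesis.SENSITIVE:
        return [f"{exposure}_p1", f"{exposure}_p2", f"{exposure}_p3"]
    period = int(h.value[-1])
    return [f"{exposure}_p{period}"]


def _exposure_block(df: pd.DataFrame, exposure: str,
                    hypothesis: TemporalHypothesis) -> pd.DataFrame:
    p1 = df[f"{exposure}_p1"].to_numpy()
    p2 = df[f"{exposure}_p2"].to_numpy()
    p3 = df[f"{exposure}_p3"].to_numpy()
    for name, v in ((f"{exposure}_p1", p1), (f"{exposure}_p2", p2),
                    (f"{exposure}_p3", p3)):
        bad = ~np.isin(v, (0, 1))
        if bad.any():
            raise ValueError(
                f"non-binary value in column {name} at row {int(np.flatnonzero(bad)[0])}")
    h = TemporalHypothesis(hypothesis)
    cols = hypothesis_columns(exposure, h)
    if h is TemporalHypothesis.FULL:
        code = 4 * p1 + 2 * p2 + p3
        data = {c: (code == int(p, 2)).astype(float)
                for c, p in zip(cols, FULL_PATTERNS)}
    elif h is TemporalHypothesis.ACCUMULATION:
        data = {cols[0]: (p1 + p2 + p3).astype(float)}
    elif h is TemporalHypothesis.SENSITIVE:
        data = {cols[0]: p1.astype(float), cols[1]: p2.astype(float),
                cols[2]: p3.astype(float)}
    else:
        period = int(h.value[-1])
        data = {cols[0]: (p1, p2, p3)[period - 1].astype(float)}
    return pd.DataFrame(data, index=df.index)


class RankDeficiencyError(ValueError):
    """Design matrix has linearly dependent columns."""


def build_design(
    cohort: pd.DataFrame,
    hypotheses: Mapping[str, TemporalHypothesis] | None = None,
    covariates: Iterable[str] | CovariateStrategy = INVARIANT_COVARIATES,
    exposures: Sequence[str] = EXPOSURES,
    check_rank: bool = True,
) -> pd.DataFrame:
    """Assemble the logistic design matrix for a cohort table.

    Parameters
    ----------
    cohort
        One row per individual with ``<exposure>_p1/_p2/_p3`` flags and
        time-invariant covariate columns.
    hypotheses
        Temporal hypothesis per exposure; exposures not listed default to FULL.
    covariates
        Time-invariant covariate columns to include (a :class:`CovariateStrategy`
        may be passed directly).
    exposures
        Which exposures contribute trajectory blocks (schema order kept).

    Returns
    -------
    pandas.DataFrame
        Columns: ``intercept``, the requested covariates, then per exposure
        the columns its hypothesis dictates.
    """
    if isinstance(covariates, CovariateStrategy):
        covariates = covariates.covariates
    hypotheses = dict(hypotheses or {})
    blocks = [pd.DataFrame({"intercept": np.ones(len(cohort))}, index=cohort.index)]
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing covariate columns: {missing}")
    if list(covariates):
        blocks.append(cohort[list(covariates)].astype(float))
    for exposure in exposures:
        h = TemporalHypothesis(hypotheses.get(exposure, TemporalHypothesis.FULL))
        blocks.append(_exposure_block(cohort, exposure, h))
    design = pd.concat(blocks, axis=1)

    constant = [c for c in design.columns[1:] if design[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant non-intercept design columns: {constant}",
                      UserWarning, stacklevel=2)
    if check_rank:
        x = design.to_numpy(float)
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # QR column pivoting: columns pivoted beyond the numerical rank
            # are the ones expressible through the others.
            _, r, piv = qr(x, mode="economic", pivoting=True)
            bad = sorted(design.columns[i] for i in piv[rank:])
            raise RankDeficiencyError(
                f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
                f"collinear columns: {bad}")
    return design
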