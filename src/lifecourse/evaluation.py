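"""Discrimination and stability diagnostics for fitted logistic models.

The concordance (c) statistic is the probability that a randomly chosen
event case receives a higher predicted probability than a randomly chosen
non-case, with ties counted as half.  Cross-validated c and nonparametric
bootstrap standard errors check that apparent discrimination and
model-based SEs are not artefacts of overfitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .glm import FitResult, fit_logistic


@dataclass(frozen=True)
class Concordance:
    c: float
    n_pairs: int
    n_concordant: int
    n_tied: int


def c_statistic(predicted, outcome) -> Concordance:
    """Pairwise concordance between predictions and a binary outcome.

    Counts, over all case/non-case pairs, how often the case's prediction is
    strictly higher (concordant) or equal (tied); ``c = (concordant +
    tied/2) / pairs``.  Computed by sorting and sweeping the distinct
    prediction values, O(n log n).
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predicted and outcome must be 1-d vectors of equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one event and one non-event")

    order = np.argsort(p, kind="mergesort")
    ps, ys = p[order], y[order]
    # group equal predictions; sweep upward keeping a running non-case count
    boundaries = np.flatnonzero(np.diff(ps)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(ps)]))
    concordant = 0
    tied = 0
    zeros_below = 0
    for a, b in zip(starts, ends):
        cases_here = int(ys[a:b].sum())
        zeros_here = (b - a) - cases_here
        concordant += cases_here * zeros_below
        tied += cases_here * zeros_here
        zeros_below += zeros_here
    n_pairs = n1 * n0
    return Concordance(c=(concordant + 0.5 * tied) / n_pairs,
                       n_pairs=n_pairs, n_concordant=concordant, n_tied=tied)


def stratified_folds(outcome, k: int, seed: int) -> np.ndarray:
    """Fold label per record: within each outcome class, shuffled round-robin.

    Handles any ``2 <= k <= n`` including leave-one-out.
    """
    y = np.asarray(outcome)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"k must be between 2 and n={n}, got {k}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    offset = 0
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)  # stagger so small folds fill evenly
    return folds


@dataclass
class CrossValidatedC:
    mean_c: float
    per_fold: list[float]  # NaN where a test fold lacks both classes
    pooled_c: float


def cv_c_statistic(
    design: pd.DataFrame,
    outcome,
    k: int = 10,
    seed: int = 0,
    fit: Callable[[pd.DataFrame, np.ndarray], FitResult] = fit_logistic,
) -> CrossValidatedC:
    """Out-of-sample concordance by stratified k-fold cross-validation.

    Per-fold c is reported where the test fold contains both outcome
    classes; ``mean_c`` averages those folds, falling back to the pooled
    out-of-fold c (all held-out predictions scored together) when no fold
    supports a per-fold value, e.g. leave-one-out.
    """
    y = np.asarray(outcome, dtype=float)
    folds = stratified_folds(y, k, seed)
    oof = np.full(len(y), np.nan)
    per_fold: list[float] = []
    for f in range(k):
        test = folds == f
        train = ~test
        res = fit(design.loc[train], y[train])
        eta = design.loc[test].to_numpy(float) @ res.coef.to_numpy()
        pred = 1.0 / (1.0 + np.exp(-eta))
        oof[test] = pred
        if 0 < y[test].sum() < test.sum():
            per_fold.append(c_statistic(pred, y[test]).c)
        else:
            per_fold.append(float("nan"))
    pooled = c_statistic(oof, y).c
    defined = [v for v in per_fold if np.isfinite(v)]
    mean_c = float(np.mean(defined)) if defined else pooled
    return CrossValidatedC(mean_c=mean_c, per_fold=per_fold, pooled_c=pooled)


def bootstrap_se(
    design: pd.DataFrame,
    outcome,
    n_boot: int = 200,
    seed: int = 0,
    fit: Callable[[pd.DataFrame, np.ndarray], FitResult] = fit_logistic,
    max_failure_rate: float = 0.10,
) -> pd.DataFrame:
    """Case-resampling bootstrap standard errors for the coefficients.

    Individuals are resampled with replacement ``n_boot`` times; the SE of
    each coefficient is the SD of its replicate estimates.  Replicates whose
    fit fails (separation, non-convergence) are dropped and counted; more
    than ``max_failure_rate`` failures raises.

    Returns a DataFrame indexed by term with columns ``se_boot`` and
    ``n_replicates``.
    """
    y = np.asarray(outcome, dtype=float)
    if n_boot < 2:
        raise ValueError(f"need at least 2 bootstrap replicates, got {n_boot}")
    if n_boot < 50:
        warnings.warn(f"B={n_boot} bootstrap replicates give unstable SEs; "
                      "50 or more recommended", UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(y)
    draws = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            res = fit(design.iloc[idx].reset_index(drop=True), y[idx])
            if not res.converged:
                raise RuntimeError("replicate fit did not converge")
            draws.append(res.coef.to_numpy())
        except Exception:
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed to fit")
    arr = np.vstack(draws)
    return pd.DataFrame(
        {"se_boot": arr.std(axis=0, ddof=1), "n_replicates": len(draws)},
        index=design.columns,
    )
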