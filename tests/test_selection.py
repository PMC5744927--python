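"""Likelihood-ratio trimming and the three-step selection rule."""

import numpy as np
import pandas as pd
import pytest

from lifecourse import (
    TemporalHypothesis,
    build_design,
    fit_logistic,
    lrt,
    select_all,
    select_for_exposure,
    simulate_trajectories,
)
from lifecourse.glm import FitResult
from lifecourse.selection import Candidate, LRTResult, _apply_rule


def _fake_fit(loglik, n_params):
    idx = [f"b{i}" for i in range(n_params)]
    return FitResult(coef=pd.Series(0.0, index=idx),
                     cov=pd.DataFrame(np.eye(n_params), index=idx, columns=idx),
                     loglik=loglik, n_params=n_params, n_obs=1000, converged=True)


def test_identical_models_give_stat_zero_p_one():
    res = lrt(_fake_fit(-500.0, 8), _fake_fit(-500.0, 2))
    assert res.stat == 0.0
    assert res.p == pytest.approx(1.0)
    assert res.df == 6


def test_chi_square_critical_value():
    # 3.841 is the classical 5% critical value of chi-square with 1 df
    res = lrt(_fake_fit(-500.0, 8), _fake_fit(-500.0 - 3.841 / 2, 7))
    assert res.df == 1
    assert res.p == pytest.approx(0.050, abs=5e-4)


def test_nesting_violation_raises():
    with pytest.raises(ValueError, match="nesting"):
        lrt(_fake_fit(-500.0, 8), _fake_fit(-499.0, 2))


def test_restricted_must_be_smaller():
    with pytest.raises(ValueError, match="fewer parameters"):
        lrt(_fake_fit(-500.0, 2), _fake_fit(-501.0, 2))


def _candidate(h, p, aic):
    return Candidate(h, LRTResult(stat=1.0, df=1, p=p), aic)


def test_selection_rule_smallest_aic_among_qualifying():
    c1 = _candidate(TemporalHypothesis.ACCUMULATION, 0.30, 1000.0)
    c2 = _candidate(TemporalHypothesis.SENSITIVE, 0.60, 1002.0)
    c3 = _candidate(TemporalHypothesis.CRITICAL_P1, 0.01, 900.0)  # fails LRT
    chosen = _apply_rule({c.hypothesis: c for c in (c1, c2, c3)}, 0.05)
    assert chosen is TemporalHypothesis.ACCUMULATION


def test_selection_rule_falls_back_to_full():
    cands = {h: _candidate(h, 0.001, 1000.0)
             for h in (TemporalHypothesis.ACCUMULATION,
                       TemporalHypothesis.SENSITIVE)}
    assert _apply_rule(cands, 0.05) is TemporalHypothesis.FULL


def _single_exposure_cohort(n, coef_by_col, hypothesis, rng,
                            rates=(0.35, 0.6, 0.25)):
    traj = simulate_trajectories(n, *rates, rng)
    cohort = pd.DataFrame({"injury_p1": traj[:, 0], "injury_p2": traj[:, 1],
                           "injury_p3": traj[:, 2]})
    design = build_design(cohort, {"injury": hypothesis}, covariates=(),
                          exposures=("injury",), check_rank=False)
    beta = pd.Series(0.0, index=design.columns)
    beta["intercept"] = -1.2
    for col, b in coef_by_col.items():
        beta[col] = b
    eta = design.to_numpy(float) @ beta.to_numpy()
    cohort["no_graduation"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return cohort


def test_accumulation_truth_selected(rng):
    cohort = _single_exposure_cohort(
        20_000, {"injury_nperiods": np.log(1.7)},
        TemporalHypothesis.ACCUMULATION, rng)
    sel = select_for_exposure(cohort, "injury", strategy="none",
                              exposures=("injury",))
    assert sel.chosen is TemporalHypothesis.ACCUMULATION
    assert sel.candidates[TemporalHypothesis.ACCUMULATION].lrt.p > 0.05


def test_aic_lrt_algebraic_link(rng):
    """AIC(full) - AIC(restricted) = 2*df - LRT stat, exactly, on real fits."""
    cohort = _single_exposure_cohort(
        5_000, {"injury_nperiods": np.log(1.5)},
        TemporalHypothesis.ACCUMULATION, rng)
    sel = select_for_exposure(cohort, "injury", strategy="none",
                              exposures=("injury",))
    for cand in sel.candidates.values():
        assert sel.full_aic - cand.aic == pytest.approx(
            2 * cand.lrt.df - cand.lrt.stat, abs=1e-5)


def test_selection_invariant_to_exposure_order(small_cohort):
    order_a = ("low_income", "mobility", "family_change", "ext_mental", "injury")
    order_b = tuple(reversed(order_a))
    tab_a = select_all(small_cohort, "birth_only", exposures=order_a)
    tab_b = select_all(small_cohort, "birth_only", exposures=order_b)
    assert tab_a.chosen == tab_b.chosen
    assert tab_a.final_fit.loglik == pytest.approx(tab_b.final_fit.loglik,
                                                   abs=1e-6)


def test_select_all_matches_select_for_exposure_single_exposure(rng):
    cohort = _single_exposure_cohort(
        8_000, {"injury_nperiods": np.log(1.6)},
        TemporalHypothesis.ACCUMULATION, rng)
    single = select_for_exposure(cohort, "injury", strategy="none",
                                 exposures=("injury",))
    table = select_all(cohort, "none", exposures=("injury",))
    assert table.chosen["injury"] is single.chosen
    assert table.selections["injury"].full_aic == pytest.approx(single.full_aic)


def test_iterative_retrim_reaches_fixed_point(small_cohort):
    one_pass = select_all(small_cohort, "birth_only")
    iterated = select_all(small_cohort, "birth_only", iterative=True)
    assert iterated.iterations >= 1
    # a second run from the iterated context must be stable
    assert set(iterated.chosen) == set(one_pass.chosen)


def test_selection_table_serialization(small_cohort):
    table = select_all(small_cohort, "birth_only")
    wide = table.to_frame()
    assert set(wide["exposure"]) == set(table.chosen)
    long = table.candidates_frame()
    assert len(long) == 5 * 6  # five exposures, six hypotheses each
    assert long.groupby("exposure")["chosen"].sum().eq(1).all()
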