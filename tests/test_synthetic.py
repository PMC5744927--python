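"""Synthetic cohort generator: chain oracle, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from lifecourse import (
    EXPOSURES,
    INVARIANT_COVARIATES,
    Scenario,
    build_design,
    default_manitoba_like_scenario,
    fit_logistic,
    fit_markov_params,
    markov_pattern_probs,
    simulate_cohort,
    simulate_trajectories,
    summarize_cohort,
    write_cohort,
)
from lifecourse.synthetic import PATTERN_COUNTS, PATTERN_ORDER

from conftest import rich_scenario


def test_all_or_nothing_chains(rng):
    always = simulate_trajectories(200, 1.0, 1.0, 0.0, rng)
    assert (always == 1).all()
    never = simulate_trajectories(200, 0.0, 0.5, 0.0, rng)
    assert (never == 0).all()


def test_pattern_probs_sum_to_one():
    assert markov_pattern_probs(0.3, 0.7, 0.1).sum() == pytest.approx(1.0)


def test_empirical_frequencies_match_chain_closed_form(rng):
    n = 100_000
    p_start, p_persist, p_incident = 0.33, 0.8, 0.08
    traj = simulate_trajectories(n, p_start, p_persist, p_incident, rng)
    probs = markov_pattern_probs(p_start, p_persist, p_incident)
    code = 4 * traj[:, 0] + 2 * traj[:, 1] + traj[:, 2]
    for pattern, p in zip(PATTERN_ORDER, probs):
        observed = float(np.mean(code == int(pattern, 2)))
        mc_se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * mc_se + 1e-12, pattern


def test_markov_moment_fit_is_exact_on_chain_distributions():
    truth = (0.31, 0.72, 0.09)
    recovered = fit_markov_params(markov_pattern_probs(*truth))
    assert recovered == pytest.approx(truth, abs=1e-12)


def test_default_scenario_reproduces_published_marginals():
    scenario = default_manitoba_like_scenario(n=50_000, seed=4)
    cohort = simulate_cohort(scenario)
    s = summarize_cohort(cohort)
    mc3 = 3 * np.sqrt(0.25 / 50_000)
    # rural and unmarried are drawn at family level and shared by siblings;
    # with half the cohort in pairs that inflates the variance 1.5-fold
    mc3_fam = 3 * np.sqrt(0.25 * 1.5 / 50_000)
    assert abs(s["prevalence"] - 0.2410) < 0.005  # intercept-calibrated
    assert abs(s["male_fraction"] - 0.5048) < mc3
    assert abs(s["rural_fraction"] - 0.4738) < mc3_fam
    assert abs(s["unmarried_fraction"] - 0.2983) < mc3_fam
    # never-exposed / always-exposed corners of the income trajectory
    target = np.array(PATTERN_COUNTS["low_income"], float)
    target /= target.sum()
    freq = s["low_income_pattern_freq"]
    for pattern, t in zip(PATTERN_ORDER, target):
        assert abs(freq.get(pattern, 0.0) - t) < 0.05


def test_zero_effect_scenario_hits_prevalence_exactly():
    scenario = rich_scenario(40_000, seed=3)
    for mech in scenario.exposures.values():
        mech.coef = tuple(0.0 for _ in mech.coef)
    scenario.covariate_coef = {k: 0.0 for k in scenario.covariate_coef}
    cohort = simulate_cohort(scenario)
    p = cohort["no_graduation"].mean()
    assert abs(p - scenario.prevalence_target) < 3 * np.sqrt(0.25 / 40_000)


def test_schema_and_binary_invariants(small_cohort):
    expected = (["id", "family_id"] + list(INVARIANT_COVARIATES)
                + [f"{e}_p{t}" for e in EXPOSURES for t in (1, 2, 3)]
                + ["no_graduation"])
    assert list(small_cohort.columns) == expected
    assert ((small_cohort["bw_low"] + small_cohort["bw_high"]) <= 1).all()
    binary = [c for c in expected if c.endswith(("_p1", "_p2", "_p3"))]
    for c in binary + ["rural", "male", "no_graduation"]:
        assert small_cohort[c].isin((0, 1)).all()


def test_same_seed_is_byte_identical(tmp_path):
    scenario = rich_scenario(2_000, seed=77)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(simulate_cohort(scenario), p1)
    write_cohort(simulate_cohort(scenario), p2)
    assert p1.read_bytes() == p2.read_bytes()
    write_cohort(simulate_cohort(scenario, seed=78), tmp_path / "c.csv")
    assert (tmp_path / "c.csv").read_bytes() != p1.read_bytes()


def test_effect_recovery_in_refit(rng):
    """Refitting the generative model recovers a known trajectory effect."""
    scenario = rich_scenario(60_000, seed=12)
    cohort = simulate_cohort(scenario)
    design = build_design(cohort)
    fit = fit_logistic(design, cohort["no_graduation"])
    truth = scenario.exposures["low_income"].coef[-1]  # the 111 pattern
    est = fit.coef["low_income_s111"]
    assert abs(est - truth) < 3 * fit.se["low_income_s111"]


def test_sibling_outcomes_uncorrelated_when_family_sd_zero():
    scenario = rich_scenario(20_000, seed=21, prop_sibling=1.0, family_sd=0.0)
    cohort = simulate_cohort(scenario)
    design = build_design(cohort)
    fit = fit_logistic(design, cohort["no_graduation"])
    resid = cohort["no_graduation"].to_numpy() - fit.fitted
    by_fam = pd.DataFrame({"fam": cohort["family_id"], "r": resid})
    pairs = by_fam.groupby("fam")["r"].agg(["first", "last", "size"])
    pairs = pairs[pairs["size"] == 2]
    r = np.corrcoef(pairs["first"], pairs["last"])[0, 1]
    assert abs(r) < 3 / np.sqrt(len(pairs))


def test_family_sd_induces_within_family_correlation():
    scenario = rich_scenario(20_000, seed=22, prop_sibling=1.0, family_sd=1.5)
    cohort = simulate_cohort(scenario)
    design = build_design(cohort)
    fit = fit_logistic(design, cohort["no_graduation"])
    resid = cohort["no_graduation"].to_numpy() - fit.fitted
    by_fam = pd.DataFrame({"fam": cohort["family_id"], "r": resid})
    pairs = by_fam.groupby("fam")["r"].agg(["first", "last", "size"])
    pairs = pairs[pairs["size"] == 2]
    r = np.corrcoef(pairs["first"], pairs["last"])[0, 1]
    assert r > 0.05


def test_scenario_yaml_round_trip(tmp_path):
    scenario = rich_scenario(500, seed=5, family_sd=0.3)
    path = tmp_path / "scenario.yaml"
    scenario.to_yaml(path)
    loaded = Scenario.from_yaml(path)
    assert loaded.to_dict() == scenario.to_dict()


def test_scenario_validation():
    with pytest.raises(ValueError, match="prevalence"):
        rich_scenario(100, prevalence_target=1.5)
    with pytest.raises(ValueError, match="coefficients"):
        from lifecourse import ExposureMechanism, TemporalHypothesis

        ExposureMechanism(TemporalHypothesis.SENSITIVE, (0.1,), 0.3, 0.5, 0.1)
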