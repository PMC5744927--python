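"""Logistic fitting against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from lifecourse import SeparationError, fit_logistic, odds_ratio_table


def _design(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame({"intercept": np.ones(n), **cols})


def test_intercept_only_closed_form():
    y = np.array([0, 1] * 25)
    fit = fit_logistic(_design(dummy=np.zeros(50)).iloc[:, :1], y)
    assert fit.coef["intercept"] == pytest.approx(0.0, abs=1e-8)
    assert fit.loglik == pytest.approx(50 * np.log(0.5), abs=1e-8)
    assert fit.converged


def test_two_by_two_closed_form_slope():
    # exposed: a events, b non-events; unexposed: c events, d non-events
    a, b, c, d = 17, 23, 11, 49
    x = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
    y = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
    fit = fit_logistic(_design(exposed=x), y)
    assert fit.coef["exposed"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
    assert fit.coef["intercept"] == pytest.approx(np.log(c / d), abs=1e-6)


def _grid_oracle_loglik(x, y, span=6.0, points=61, levels=5):
    """Brute-force maximum of the Bernoulli log-likelihood on a shrinking grid."""
    def loglik(b0, b1):
        eta = b0 + b1 * x
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    c0 = c1 = 0.0
    half = span
    best = -np.inf
    for _ in range(levels):
        g0 = np.linspace(c0 - half, c0 + half, points)
        g1 = np.linspace(c1 - half, c1 + half, points)
        vals = np.array([[loglik(a, b) for b in g1] for a in g0])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best, c0, c1 = vals[i, j], g0[i], g1[j]
        half /= points / 4
    return best


def test_loglik_matches_grid_search_oracle(rng):
    x = rng.normal(size=20)
    y = (rng.random(20) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
    fit = fit_logistic(_design(x=x), y)
    assert fit.loglik == pytest.approx(_grid_oracle_loglik(x, y), abs=1e-4)


def test_aic_identity_and_cov_psd(rng):
    x = rng.normal(size=200)
    y = (rng.random(200) < 0.4).astype(float)
    fit = fit_logistic(_design(x=x), y)
    assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
    cov = fit.cov.to_numpy()
    assert np.allclose(cov, cov.T)
    assert np.linalg.eigvalsh(cov).min() >= -1e-10


def test_adding_a_column_never_decreases_loglik(rng):
    for _ in range(5):
        x = rng.normal(size=150)
        z = rng.normal(size=150)
        y = (rng.random(150) < 1 / (1 + np.exp(-x))).astype(float)
        base = fit_logistic(_design(x=x), y)
        bigger = fit_logistic(_design(x=x, z=z), y)
        assert bigger.loglik >= base.loglik - 1e-7


def test_fitted_mean_equals_event_rate(rng):
    x = rng.normal(size=500)
    y = (rng.random(500) < 1 / (1 + np.exp(-(0.5 + x)))).astype(float)
    fit = fit_logistic(_design(x=x), y)
    assert fit.fitted.mean() == pytest.approx(y.mean(), abs=1e-8)


def test_coefficient_recovery_at_scale(rng):
    n = 50_000
    x1 = rng.normal(size=n)
    x2 = (rng.random(n) < 0.3).astype(float)
    truth = {"intercept": -1.0, "x1": 0.6, "x2": -0.4}
    eta = truth["intercept"] + truth["x1"] * x1 + truth["x2"] * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(_design(x1=x1, x2=x2), y)
    for term, b in truth.items():
        assert abs(fit.coef[term] - b) < 3 * fit.se[term]


def test_separation_raises_naming_column():
    x = np.repeat([0.0, 1.0], 25)
    y = x.copy()  # x separates y perfectly
    with pytest.raises(SeparationError, match="sep_col"):
        fit_logistic(_design(sep_col=x), y)


def test_more_params_than_rows_rejected(rng):
    x = rng.normal(size=3)
    with pytest.raises(ValueError, match="observations"):
        fit_logistic(_design(a=x, b=x * 2, c=x + 1), np.array([0.0, 1.0, 0.0]))


def test_or_table_null_coefficient_symmetric():
    rng = np.random.default_rng(3)
    x = np.tile([0.0, 1.0], 100)
    y = np.tile([0.0, 1.0, 1.0, 0.0], 50)  # x carries no signal
    fit = fit_logistic(_design(x=x), y)
    row = odds_ratio_table(fit).set_index("term").loc["x"]
    assert row["OR"] == pytest.approx(1.0, abs=1e-6)
    # CI symmetric about OR on the log scale
    assert np.log(row["ci_high"]) - np.log(row["OR"]) == pytest.approx(
        np.log(row["OR"]) - np.log(row["ci_low"]), abs=1e-10)


def test_or_table_matches_cross_product_on_aggregated_counts():
    # printed-count layout: non-graduates/graduates for always- vs never-exposed
    a, b = 7761, 6598  # exposed in all three periods
    c, d = 6987, 45634  # never exposed
    design = _design(exposed=np.array([1.0, 1.0, 0.0, 0.0]))
    y = np.array([1.0, 0.0, 1.0, 0.0])
    fit = fit_logistic(design, y, weights=np.array([a, b, c, d], float))
    table = odds_ratio_table(fit).set_index("term")
    assert table.loc["exposed", "OR"] == pytest.approx(a * d / (b * c), rel=1e-6)
    assert table.loc["exposed", "OR"] == pytest.approx(7.68, abs=0.01)


def test_or_table_rejects_bad_level(rng):
    x = rng.normal(size=60)
    y = (rng.random(60) < 0.5).astype(float)
    fit = fit_logistic(_design(x=x), y)
    with pytest.raises(ValueError, match="level"):
        odds_ratio_table(fit, level=1.2)


def test_fit_result_json_round_trip(rng):
    import json

    x = rng.normal(size=80)
    y = (rng.random(80) < 0.5).astype(float)
    fit = fit_logistic(_design(x=x), y)
    payload = json.loads(fit.to_json())
    assert payload["terms"] == ["intercept", "x"]
    assert payload["aic"] == pytest.approx(fit.aic)
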