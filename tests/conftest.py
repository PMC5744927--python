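import numpy as np
import pytest

from lifecourse import (
    EXPOSURES,
    ExposureMechanism,
    Scenario,
    TemporalHypothesis,
    simulate_cohort,
)

# Mechanism rates boosted relative to the registry-like defaults so that all
# eight trajectory patterns occur even in cohorts of a few thousand; effect
# magnitudes stay in the published range.
_RICH_MECHS = {
    "low_income": ExposureMechanism(
        TemporalHypothesis.FULL,
        tuple(np.log([1.3, 1.5, 1.7, 1.7, 2.0, 1.9, 3.2])),
        0.35, 0.65, 0.25),
    "mobility": ExposureMechanism(
        TemporalHypothesis.FULL,
        tuple(np.log([1.05, 1.1, 1.2, 1.3, 1.2, 1.6, 1.7])),
        0.40, 0.55, 0.30),
    "family_change": ExposureMechanism(
        TemporalHypothesis.FULL,
        tuple(np.log([1.05, 1.25, 1.25, 0.95, 1.05, 1.35, 1.15])),
        0.30, 0.45, 0.25),
    "ext_mental": ExposureMechanism(
        TemporalHypothesis.SENSITIVE, tuple(np.log([1.25, 1.3, 1.6])),
        0.25, 0.55, 0.20),
    "injury": ExposureMechanism(
        TemporalHypothesis.ACCUMULATION, (float(np.log(1.35)),),
        0.30, 0.40, 0.25),
}

_COV_COEF = {
    "mother_age_first_birth": float(np.log(0.98)),
    "family_size": float(np.log(1.28)),
    "birth_order": float(np.log(1.13)),
    "rural": float(np.log(1.32)),
    "mother_unmarried": float(np.log(2.03)),
    "male": float(np.log(1.17)),
    "bw_low": float(np.log(0.94)),
    "bw_high": float(np.log(0.99)),
    "birth_year": float(np.log(0.94)),
    "low_grade9": float(np.log(11.71)),
}


def rich_scenario(n: int, seed: int = 0, **overrides) -> Scenario:
    """Pattern-rich five-exposure scenario usable at small cohort sizes."""
    fields = dict(n=n, exposures=dict(_RICH_MECHS), covariate_coef=dict(_COV_COEF),
                  seed=seed)
    fields.update(overrides)
    return Scenario(**fields)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3,000-person cohort covering all patterns of all five exposures."""
    return simulate_cohort(rich_scenario(3_000, seed=11))


@pytest.fixture(scope="session")
def small_cohort_path(small_cohort, tmp_path_factory):
    from lifecourse import write_cohort

    path = tmp_path_factory.mktemp("cohort") / "cohort.csv"
    write_cohort(small_cohort, path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
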