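"""Shared fixtures: simulated cohorts reused across the suite."""

import pytest

import pptrial as pt

#: adjustment sets matching the preset scenarios' data-generating models
ANALYSIS_CONFIG = pt.AnalysisConfig(
    baseline_covariates=("age_std", "cvd_history"),
    time_varying_covariates=("severity",),
)
CRUDE_CONFIG = pt.AnalysisConfig(unadjusted=True)


def make_cohort(scenario: str, n: int, seed: int, **build_kw):
    config = pt.preset_scenario(scenario, n_participants=n, seed=seed)
    raw = pt.generate_cohort(config)
    table = pt.build_person_quarters(raw, pt.BuildConfig(**build_kw))
    return config, raw, table


@pytest.fixture(scope="session")
def analysis_config():
    return ANALYSIS_CONFIG


@pytest.fixture(scope="session")
def confounded_cohort():
    """n=20 000 confounded + informative-censoring cohort (seed 42)."""
    return make_cohort("confounded", 20_000, 42)


@pytest.fixture(scope="session")
def null_cohort():
    """n=20 000 cohort with treatment, censoring and outcome independent."""
    return make_cohort("null_confounding", 20_000, 11)


@pytest.fixture(scope="session")
def proportional_cohort():
    """n=20 000 cohort with a constant regimen odds effect of 1.5."""
    return make_cohort("proportional_effect", 20_000, 500)


@pytest.fixture(scope="session")
def small_cohort():
    """200-participant cohort for exact small-sample checks."""
    return make_cohort("confounded", 200, 9)
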