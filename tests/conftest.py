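import pytest

import epmed


@pytest.fixture(scope="session")
def cohort():
    """Study-scale cohort with the default (headline) path effects."""
    return epmed.generate(epmed.default_config(seed=11))


@pytest.fixture(scope="session")
def frame(cohort):
    return epmed.cohort_frame(cohort)


@pytest.fixture(scope="session")
def spec(cohort):
    return epmed.ModelSpec(
        predictors=list(cohort.genotypes.markers), n_boot=500, seed=3
    )


@pytest.fixture(scope="session")
def estimates(frame, spec):
    return epmed.fit_path_model(frame, spec)


@pytest.fixture(scope="session")
def trial_cohort():
    """Small cohort with raw trial tables attached."""
    cfg = epmed.default_config(
        seed=13, emit_trials=True, n_families=40, n_controls=30
    )
    return epmed.generate(cfg)
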