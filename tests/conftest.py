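import warnings

import pytest

import gesturelab as gl


@pytest.fixture(scope="session")
def default_params():
    return gl.default_params()


@pytest.fixture(scope="session")
def default_cohort(default_params):
    """Seeded completer cohort (10 novices, 6 experienced, 3x3 cells each)."""
    design = gl.completer_design()
    return gl.sample_cohort(design, default_params, seed=1)


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    return gl.features_table(default_cohort)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Zero-reference-SD cells and constant-column drops are expected on
    synthetic cohorts (gestures absent from a module); keep test output clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*zero reference SD.*")
        warnings.filterwarnings("ignore", message=".*constant feature column.*")
        yield
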