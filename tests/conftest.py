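import numpy as np
import pytest

from traumacast.io import packaged_scenario_path
from traumacast.screening import ScreeningRuleSet, StudyEstimate


def make_record(study_id="s1", sample_id=None, n=100, events=None, prevalence=0.2,
                method="clinical", months=6.0, prevalence_type="point",
                population="general", exposure_specific="yes", wave=None,
                reanalysis_of=None):
    """Terse builder for a valid record with overridable screening metadata."""
    return StudyEstimate(
        study_id=study_id,
        sample_id=sample_id or f"{study_id}a",
        n=n,
        events=events,
        prevalence=prevalence if events is None else None,
        method=method,
        months_post_exposure=months,
        prevalence_type=prevalence_type,
        population=population,
        exposure_specific=exposure_specific,
        wave=wave,
        reanalysis_of=reanalysis_of,
    )


@pytest.fixture
def rules():
    return ScreeningRuleSet()


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def table_scenario():
    return packaged_scenario_path("national_table")


@pytest.fixture(scope="session")
def model_scenario():
    return packaged_scenario_path("national_model")
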