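import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for defeasible_oracle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def case_study_config():
    from cdl_sentinel.scenario_cli import bundled_scenario_path, load_scenario

    return load_scenario(bundled_scenario_path("parkinsons_case_study"))


@pytest.fixture(scope="session")
def netlogo_config():
    from cdl_sentinel.scenario_cli import bundled_scenario_path, load_scenario

    return load_scenario(bundled_scenario_path("netlogo_replica"))
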