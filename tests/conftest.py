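import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for kf_oracle

from quitrate.synthetic import EtaTrajectory, ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic scenario (group-2 ramp), fixed seed."""
    return generate_scenario(seed=42)


@pytest.fixture(scope="session")
def constant_truth_config():
    """Constant rates (0.045, 0.025, 0.055), the recovery-study conditions."""
    return ScenarioConfig(
        eta_trajectories=(
            EtaTrajectory("constant", 0.045),
            EtaTrajectory("constant", 0.025),
            EtaTrajectory("constant", 0.055),
        )
    )
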