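import pytest

from pathshade.model import PathChoiceModel
from pathshade.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study_decisions():
    """A study-sized synthetic cohort (46 x 13, all trials in sun)."""
    frame, truth = simulate_study(SimulationConfig(seed=20260101))
    return frame, truth


@pytest.fixture(scope="session")
def small_fit():
    """A quick posterior fit on a small cohort, shared by several tests."""
    frame, truth = simulate_study(SimulationConfig(n_participants=24, seed=7))
    frame = frame[~frame["is_test"]]
    model = PathChoiceModel(frame)
    results = model.fit(chains=2, tune=400, draws=600, seed=7)
    return model, results, truth
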