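import numpy as np
import pytest

from pawshift import CohortModel, TrialTimeline


@pytest.fixture(scope="session")
def fast_timeline() -> TrialTimeline:
    """A scaled-down timeline for quick end-to-end runs.

    Same structure as the experiment (baseline / pairing / threat+hold) but
    shorter epochs and a lower camera rate; all analysis code paths are
    rate- and duration-agnostic.
    """
    return TrialTimeline(pairing_start=12.0, threat_onset=24.0, threat_hold=4.0, frame_rate=50.0)


@pytest.fixture(scope="session")
def small_model() -> CohortModel:
    return CohortModel(n_mice=2, n_sessions=1, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
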