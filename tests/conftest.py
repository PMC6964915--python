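import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from condesign import CueSet, PeriodicDesign, Stage, StageWiseDesign


@pytest.fixture(scope="session")
def single_cue_set():
    return CueSet(("CS",))


@pytest.fixture(scope="session")
def ab_cue_set():
    return CueSet(("A", "B"), (("A", "B"),))


@pytest.fixture(scope="session")
def backward_blocking_design(ab_cue_set):
    z = {"A": 0.0, "B": 0.0, "AB": 0.0}
    return StageWiseDesign(
        ab_cue_set,
        (
            Stage(20, {**z, "AB": 1.0}, {"A": 0.0, "B": 0.0, "AB": 1.0}),
            Stage(20, {**z, "A": 1.0}, {"A": 1.0, "B": 0.0, "AB": 0.0}),
            Stage(10, {"A": 0.5, "B": 0.5, "AB": 0.0},
                  {"A": 0.0, "B": 0.0, "AB": 0.0}),
        ),
    )


@pytest.fixture(scope="session")
def always_reinforced(single_cue_set):
    return StageWiseDesign(
        single_cue_set, (Stage(40, {"CS": 1.0}, {"CS": 1.0}),)
    )


@pytest.fixture(scope="session")
def reversal_rich(single_cue_set):
    """A periodic single-cue design with frequent contingency switches."""
    return PeriodicDesign(single_cue_set, 200, {"CS": (1.0, 1.0)},
                          {"CS": (0.9, 0.1)}, 0.125)
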