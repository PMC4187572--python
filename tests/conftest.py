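import pytest

from musclebold.paradigm import AcquisitionParams, ExerciseParadigm
from musclebold.pipeline import run_synthetic
from musclebold.presets import get_preset, study_acquisition, study_paradigm


@pytest.fixture(scope="session")
def paradigm() -> ExerciseParadigm:
    """Published block design: 60 s baseline + 4 x (90 s exercise + 120 s recovery)."""
    return study_paradigm()


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    """Published acquisition: TR 3 s, TE 21/60 ms, 80x80 over 200 mm, 10x5 mm, 300 frames."""
    return study_acquisition()


@pytest.fixture(scope="session")
def fast_preset():
    return get_preset("fast")


@pytest.fixture(scope="session")
def noiseless_run():
    """Full noiseless pipeline on the fast preset with default injected truth."""
    return run_synthetic("fast", seed=0, snr=None, muscles=("soleus", "gastrocnemius"))
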