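import warnings

import numpy as np
import pytest

from imugait import PipelineConfig
from imugait.preprocess import preprocess
from imugait.synthetic import gen_session, gen_tug, gen_walk

FS = 31.25


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def walk_trial():
    """One default walking trial with its aligned signal (cadence 1.8 Hz)."""
    rec, truth = gen_walk(f_step=1.8, n_steps=20, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig = preprocess(rec)
    return rec, truth, sig


@pytest.fixture(scope="session")
def tug_trial():
    """One default scripted timed-up-and-go trial with its aligned signal."""
    rec, truth = gen_tug(seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig = preprocess(rec)
    return rec, truth, sig


@pytest.fixture(scope="session")
def session_data():
    """A complete synthetic session (recordings, annotations, meta, truths)."""
    return gen_session(seed=5)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        yield
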