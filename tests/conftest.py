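import numpy as np
import pytest

import psyconf as pc
from psyconf.params import subject_like_params


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def task_A():
    return pc.task_a()


@pytest.fixture(scope="session")
def task_B():
    return pc.task_b()


@pytest.fixture(scope="session")
def exp1():
    return pc.experiment1_structure()


@pytest.fixture(scope="session")
def small_structure():
    """One session, one Task-A part, tiny blocks: fast end-to-end runs."""
    return pc.SessionStructure(n_sessions=1, tasks_per_session=("A",),
                               category_training_blocks=(1, 8),
                               confidence_training_blocks=(1, 4),
                               testing_blocks=(2, 40))


@pytest.fixture(scope="session")
def taska_4320():
    """Session structure giving 4320 Task-A testing trials."""
    return pc.SessionStructure(tasks_per_session=("A",), testing_blocks=(3, 288))


@pytest.fixture
def make_params():
    """Behaviorally plausible parameter draws, seeded per call."""

    def _make(model_name, seed=0, **overrides):
        model = pc.get_model(model_name)
        pv = subject_like_params(model, np.random.default_rng(seed))
        if overrides:
            vals = pv.natural_dict()
            vals.update(overrides)
            pv = pc.ParamVector.from_dict(model, vals)
        return model, pv

    return _make
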