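import numpy as np
import pytest

from rlbold import TaskConfig, generate_schedule, simulate_agent
from rlbold.rl import SubjectParams


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig(seed=7)


@pytest.fixture(scope="session")
def one_block_schedule(default_config):
    return generate_schedule(default_config, 1)


@pytest.fixture(scope="session")
def reversal_schedule():
    return generate_schedule(TaskConfig(seed=21), 8, reversal_at_block=5)


@pytest.fixture(scope="session")
def proficient_record(reversal_schedule):
    """A well-learning agent simulated through acquisition and reversal."""
    params = SubjectParams(alpha=0.4, beta0=-1.0, beta1=8.0)
    return simulate_agent(reversal_schedule, params, seed=5)


def naive_forward_pass(odor, choice, reward, alpha):
    """Trial-by-trial reference recursion, independent of the filtered one."""
    q = np.zeros((3, 2))
    dv = np.zeros(len(odor))
    for t in range(len(odor)):
        o, c, r = odor[t], choice[t], reward[t]
        dv[t] = q[o, 1] - q[o, 0]
        q[o, c] = q[o, c] + alpha * (r - q[o, c])
    return dv
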