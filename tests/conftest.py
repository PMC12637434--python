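import numpy as np
import pytest

from revalue.agents import RLParamsQ
from revalue.behavior import params_from_dict
from revalue.preprocess import apply_trial_exclusions
from revalue.task import TaskConfig
from revalue.values import extract_decision_variables, simulate_on_policy


#: canonical Q-learning parameters used across fixtures (moderate learning,
#: decisive value weight — produces clear win-stay behavior on the task)
CANONICAL_Q = dict(
    alpha_rew=0.3, alpha_stay=0.3, gamma_forget=0.2,
    beta_rew=4.0, beta_stay=1.0, bias=0.0,
)


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def q_params():
    return params_from_dict("q_cs", CANONICAL_Q)


@pytest.fixture(scope="session")
def small_session(task_config, q_params):
    """A 120-trial on-policy session with edge trials excluded (100 kept)."""
    sess, _ = simulate_on_policy(q_params, task_config, 120, seed=5)
    filtered, _ = apply_trial_exclusions(sess)
    return filtered


@pytest.fixture(scope="session")
def small_trajectories(small_session, q_params):
    return extract_decision_variables(small_session, q_params)
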