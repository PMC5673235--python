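import pytest

from tdhybrid import models, synthetic, task


@pytest.fixture(scope="session")
def default_task():
    return task.build_task({})


@pytest.fixture(scope="session")
def acq_lambda():
    return models.get_model("ACQ(lambda)")


@pytest.fixture(scope="session")
def good_learner_params(acq_lambda):
    """ACQ(lambda) at the Good-learner group-mean parameters."""
    return acq_lambda.params(
        {
            "alpha": 0.588,
            "lam": 0.682,
            "w_q": 0.661,
            "tau": 0.404,
            "beta_r": 0.230,
            "beta_0": 0.093,
            "lam_beta": 0.621,
        }
    )


@pytest.fixture(scope="session")
def acq_session(default_task, acq_lambda, good_learner_params):
    """One clean simulated ACQ(lambda) session on the default task."""
    return synthetic.simulate_agent(acq_lambda, good_learner_params, default_task, seed=11)
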