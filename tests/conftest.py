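import warnings

import numpy as np
import pytest

from cuedfood import inference, synthetic


@pytest.fixture(scope="session")
def small_study():
    """A 5-subject, 5-session synthetic study with stable subjects."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.simulate_study(n_subjects=5, seed=20240)


@pytest.fixture(scope="session")
def natural_subject_trials():
    """100 study-shaped trials from one subject at the published natural-cued
    session-1 group means."""
    from cuedfood.params import RstDDMParams

    means, _ = synthetic.group_param_spec("natural", 1)
    truth = RstDDMParams(**means)
    trials = inference.simulate_cohort_trials([truth], 100, seed=314)[0]
    return truth, trials


@pytest.fixture(scope="session")
def desk_cfg():
    return inference.desk_optimizer_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
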