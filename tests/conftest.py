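import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from neuromusc.body import default_model
from neuromusc.metrics import peak_metrics
from neuromusc.optimize import solve_trajectory
from neuromusc.tasks import default_tasks, estimate_1rm, generate_trial

EXPERIMENT_SEED = 2024


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def tasks():
    return default_tasks()


@pytest.fixture(scope="session")
def max_moments(model, tasks):
    return estimate_1rm(model, tasks)


@pytest.fixture(scope="session")
def default_experiment(model, tasks, max_moments):
    """The full default study: 7 tasks x 10 replicates, solved, with
    per-trial metric sets (shared across tests for speed)."""
    trials, metric_sets = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for spec in tasks.values():
            for rep in range(spec.replicates):
                tr = generate_trial(spec, rep, EXPERIMENT_SEED, model,
                                    max_moments=max_moments)
                tr = solve_trajectory(tr, model)
                trials.append(tr)
                metric_sets.append(peak_metrics(tr, model))
    return {"trials": trials, "metric_sets": metric_sets,
            "seed": EXPERIMENT_SEED}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
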