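import numpy as np
import pandas as pd
import pytest

from metacog import (SimObserverConfig, TrialTable, simulate_observer,
                     tabulate_ratings)


def make_trials(stimulus, response, confidence, k, **extra):
    df = pd.DataFrame({"participant": 1, "stimulus": stimulus,
                       "response": response, "confidence": confidence})
    for name, col in extra.items():
        df[name] = col
    return TrialTable(df, k)


def random_trials(rng, n, k=4):
    """Arbitrary (not SDT-generated) trials for oracle comparisons."""
    stim = rng.integers(1, 3, n)
    resp = rng.integers(1, 3, n)
    conf = rng.integers(1, k + 1, n)
    return make_trials(stim, resp, conf, k)


@pytest.fixture(scope="session")
def ideal_trials_large():
    """100k trials from an ideal SDT observer (d'=1.5, c=0, 4-point scale)."""
    cfg = SimObserverConfig(d_prime=1.5, c=0.0, conf_criteria=(0.5, 1.0, 1.5),
                            sigma_meta=0.0, n_trials=100_000, seed=101)
    return simulate_observer(cfg)


@pytest.fixture(scope="session")
def ideal_counts_large(ideal_trials_large):
    return tabulate_ratings(ideal_trials_large)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
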