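import numpy as np
import pandas as pd
import pytest

from driftsem.ddm import DiffusionParams, sample_first_passage


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def reference_trials():
    """192 trials from a mid-accuracy parameter set, shared across tests."""
    gen = np.random.default_rng(7)
    params = DiffusionParams(v=3.62, a=1.0, t0=0.3, st0=0.2)
    rt, correct = sample_first_passage(params, 192, gen)
    return params, pd.DataFrame({"rt_s": rt, "correct": correct})


def make_trials(params: DiffusionParams, n: int, seed: int, **labels) -> pd.DataFrame:
    gen = np.random.default_rng(seed)
    rt, correct = sample_first_passage(params, n, gen)
    df = pd.DataFrame(
        {
            "participant": labels.get("participant", "p1"),
            "task": labels.get("task", "task"),
            "condition": labels.get("condition", "cond"),
            "trial_index": np.arange(n),
            "rt_s": rt,
            "correct": correct,
        }
    )
    return df
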