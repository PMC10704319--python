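import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from peerselect.synthetic import GeneratorConfig, generate_trial

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def trial_dataset():
    """One default synthetic trial, shared across tests."""
    return generate_trial(GeneratorConfig(rng_seed=1))


@pytest.fixture(scope="session")
def trial_shaped_tables():
    """A hand-built dataset reproducing the trial's exact label counts:
    309 indexes, 60 distributors, 73 promoters, 23 detectors."""
    n = 309
    indexes = pd.DataFrame({"index_id": [f"I{i:04d}" for i in range(n)]})
    rows = []
    k = 0
    for i in range(n):
        n_alt = 2 if i < 60 else (1 if i < 73 else 0)
        for j in range(n_alt):
            is_ft = int(j == 0 and i < 73)
            is_pos = int(j == 0 and i < 23)
            rows.append((f"A{k}", f"I{i:04d}", is_ft, is_pos))
            k += 1
    alters = pd.DataFrame(rows, columns=["alter_id", "index_id", "is_first_time", "is_positive"])
    return indexes, alters


def stub_model(probs: np.ndarray):
    """A stand-in fitted model emitting fixed class-1 probabilities."""

    class _Stub:
        def __init__(self, p):
            self.p = np.asarray(p, dtype=float)

        def predict_proba1(self, X):
            return self.p[: len(X)]

    return _Stub(probs)
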