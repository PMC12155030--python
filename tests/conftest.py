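import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ehrcausal.dgp import CohortTable

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_cohort(W: np.ndarray, A, Delta, Y, **hidden) -> CohortTable:
    """Assemble a CohortTable from explicit arrays; Y entries for unmonitored
    records are masked regardless of the values passed."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != len(A):
        W = W.T
    cols = {f"W{j + 1}": W[:, j] for j in range(W.shape[1])}
    cols["A"] = np.asarray(A, dtype=int)
    cols["Delta"] = np.asarray(Delta, dtype=int)
    y = pd.array(np.asarray(Y, dtype="float"), dtype="Int64")
    y[np.asarray(Delta) == 0] = pd.NA
    cols["Y"] = y
    for k, v in hidden.items():
        cols[k] = np.asarray(v)
    return CohortTable(pd.DataFrame(cols), n_covariates=W.shape[1])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
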