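import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from adlmsm import reference
from adlmsm.ctmc import build_intensity_matrix
from adlmsm.panel_data import PanelDataset


def expm_series(M: np.ndarray, n_terms: int = 50) -> np.ndarray:
    """Independent matrix-exponential oracle: truncated power series."""
    M = np.asarray(M, dtype=float)
    out = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    for k in range(1, n_terms + 1):
        term = term @ M / k
        out = out + term
    return out


def make_dataset(rows, schema=None) -> PanelDataset:
    """Build a PanelDataset from (subject, time, state, *covariate values) tuples."""
    schema = schema or {}
    cols = ["subject_id", "time", "state", *schema]
    return PanelDataset(pd.DataFrame(rows, columns=cols), schema)


@pytest.fixture(scope="session")
def reference_Q() -> np.ndarray:
    """Generator assembled from the published intensity estimates."""
    return build_intensity_matrix(dict(reference.INTENSITIES))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240314)
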