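import numpy as np
import pandas as pd
import pytest

from omicregnet.io import OmicsMatrix, SurvivalTable


def make_survival(eta: np.ndarray, rng: np.random.Generator,
                  censor_frac: float = 0.0, scale: float = 1.0) -> SurvivalTable:
    """Exponential-hazard survival times with log-hazard ``eta``."""
    n = len(eta)
    t = rng.exponential(scale, n) / np.exp(eta)
    event = np.ones(n, dtype=int)
    if censor_frac > 0:
        c = rng.exponential(scale / censor_frac, n) / np.exp(eta)
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    idx = pd.Index([f"S{i:04d}" for i in range(n)])
    return SurvivalTable(pd.DataFrame({"time": t + 1e-6, "event": event}, index=idx))


def standardized_frame(X: np.ndarray, prefix: str = "f") -> pd.DataFrame:
    X = np.asarray(X, dtype=float)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    return pd.DataFrame(
        X,
        index=[f"S{i:04d}" for i in range(X.shape[0])],
        columns=[f"{prefix}{j:03d}" for j in range(X.shape[1])],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    vals = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 1.0, 0.5, 2.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return OmicsMatrix(values=vals, omics_kind="mRNA")
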