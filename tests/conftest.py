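import numpy as np
import pandas as pd
import pytest

from mdirt.cohort_io import DiagnosisMatrix


def make_matrix(values, patients=None, conditions=None) -> DiagnosisMatrix:
    """Build a DiagnosisMatrix from a nested list (None marks missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n, m = arr.shape
    patients = patients or [f"P{i}" for i in range(n)]
    conditions = conditions or [f"c{j}" for j in range(m)]
    return DiagnosisMatrix(pd.DataFrame(arr, index=patients, columns=conditions))


def simulate_1pl(rng, n, beta, a=1.7, mu=0.0, sigma=1.0, slopes=None) -> DiagnosisMatrix:
    """Simulate a single-class IRT matrix (per-item slopes optional)."""
    from scipy.special import expit

    beta = np.asarray(beta, dtype=float)
    theta = rng.normal(mu, sigma, n)
    s = np.full(len(beta), a) if slopes is None else np.asarray(slopes, dtype=float)
    X = (rng.random((n, len(beta))) < expit(s * (theta[:, None] - beta))).astype(float)
    return DiagnosisMatrix(
        pd.DataFrame(X, index=[f"P{i}" for i in range(n)], columns=[f"i{j}" for j in range(len(beta))])
    )


@pytest.fixture
def tiny_matrix() -> DiagnosisMatrix:
    """3 patients x 4 conditions with one missing cell."""
    return make_matrix(
        [[1, 0, 1, 0], [0, 1, None, 1], [1, 1, 0, 0]],
        patients=["A", "B", "C"],
        conditions=["hypertension", "diabetes", "depression", "anemia"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20181126)
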