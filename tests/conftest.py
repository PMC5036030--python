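import numpy as np
import pandas as pd
import pytest

import occufp as o


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated survey used by several fitting/selection tests."""
    cfg = o.SimulationConfig(
        n_sites=400,
        n_replicates=6,
        beta_psi={"(Intercept)": 0.2, "pop": -0.9, "rug": 0.7},
        alpha_p={"(Intercept)": 0.4, "elev": 0.4},
        p10=0.03,
        seed=42,
    )
    return o.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20160926)


def random_problem(rng, M=6, J=4, misclassification=False, with_missing=False,
                   replicate_p=False):
    """A random likelihood problem + parameter vector (helper, not a fixture)."""
    Xpsi = o.DesignMatrix(
        np.column_stack([np.ones(M), rng.normal(size=(M, 2))]),
        ("(Intercept)", "a", "b"),
    )
    if replicate_p:
        # replicate-level detection design passes as a raw (M, J, k) array
        Xp = np.dstack([np.ones((M, J)), rng.normal(size=(M, J))])
    else:
        Xp = o.DesignMatrix(
            np.column_stack([np.ones(M), rng.normal(size=M)]), ("(Intercept)", "c")
        )
    y = rng.integers(0, 2, size=(M, J)).astype(float)
    if with_missing:
        y[rng.integers(0, M), rng.integers(0, J)] = np.nan
    prob = o.LikelihoodProblem(y, Xpsi, Xp, misclassification)
    k = 3 + 2 + (1 if misclassification else 0)
    theta = rng.normal(size=k)
    params = o.ParameterVector.unflatten(theta, 3, 2, misclassification)
    return prob, params
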