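import numpy as np
import pytest

from structgs import SimConfig, simulate_structured_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """Three diverged subpopulations, 60 individuals each, 800 markers."""
    cfg = SimConfig(n_subpops=3, n_per_subpop=60, n_markers=800, fst=0.3,
                    missing_rate=0.0, seed=11)
    G, truth = simulate_structured_genotypes(cfg)
    return cfg, G, truth


@pytest.fixture(scope="session")
def panmictic_panel():
    """Single unstructured population used for GBLUP-style fits."""
    cfg = SimConfig(n_subpops=1, n_per_subpop=200, n_markers=1000, fst=0.0,
                    missing_rate=0.0, seed=7)
    G, truth = simulate_structured_genotypes(cfg)
    return cfg, G, truth


def dense_restricted_loglik(y, V):
    """Independent dense restricted log-likelihood with a 1-column design.

    -1/2 [ (n-p) ln 2pi + ln|V| + ln|X'V^-1 X| + y'Py ].
    """
    n = len(y)
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    _, logdetV = np.linalg.slogdet(V)
    _, logdetX = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdetV + logdetX + quad)
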