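import itertools
from pathlib import Path

import numpy as np
import pytest

from glowsplit.spectra import DEFAULT_BASIS


@pytest.fixture(scope="session")
def basis():
    return DEFAULT_BASIS


def trapezoid_oracle(y, x):
    """Independent composite-trapezoid quadrature (no numpy.trapezoid)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    total = 0.0
    for i in range(len(x) - 1):
        total += 0.5 * (y[i] + y[i + 1]) * (x[i + 1] - x[i])
    return total


def nnls_support_oracle(A, c):
    """Exhaustive NNLS for a 3-column system: try all 8 support subsets.

    For each subset S of {0,1,2}, solve the unconstrained least squares
    restricted to S, discard solutions with negative entries, and return the
    feasible solution with minimal residual norm.
    """
    A = np.asarray(A, float)
    c = np.asarray(c, float)
    best = (np.inf, np.zeros(3))
    for r in range(4):
        for S in itertools.combinations(range(3), r):
            beta = np.zeros(3)
            if S:
                sub = A[:, list(S)]
                sol, *_ = np.linalg.lstsq(sub, c, rcond=None)
                if np.any(sol < 0):
                    continue
                beta[list(S)] = sol
            resid = np.linalg.norm(c - A @ beta)
            if resid < best[0] - 1e-15:
                best = (resid, beta)
    return best[1], best[0]


@pytest.fixture(scope="session")
def supplementary_dir():
    """Local copy of the supplementary spectral/photo archive, if present."""
    path = Path(__file__).resolve().parent.parent / "data" / "supplementary"
    if not path.is_dir():
        pytest.skip("supplementary data archive not present")
    return path
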