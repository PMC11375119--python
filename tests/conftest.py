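"""Shared fixtures: synthetic geometries and calibrated models.

Expensive fixtures are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from wristnull.synthetic import (MuscleGeometry, make_wrist_geometry,
                                 simulate_calibration_session)


@pytest.fixture(scope="session")
def geometry():
    return make_wrist_geometry(seed=0)


@pytest.fixture(scope="session")
def quiet_geometry(geometry):
    """Same geometry, zero envelope noise."""
    return MuscleGeometry(H_true=geometry.H_true,
                          alpha_rest=geometry.alpha_rest,
                          cocontraction_pattern=geometry.cocontraction_pattern,
                          noise_sigma=0.0, seed=geometry.seed)


@pytest.fixture(scope="session")
def calibrated(quiet_geometry):
    """(MvfResult, EmgForceResults, NullspaceModel) from a noiseless run."""
    session = simulate_calibration_session(quiet_geometry, rounds=2,
                                           mvf_rounds=1, seed=7)
    return session.calibrate()


@pytest.fixture(scope="session")
def model(calibrated):
    return calibrated[2]


@pytest.fixture(scope="session")
def noisy_session(geometry):
    return simulate_calibration_session(geometry, rounds=6, mvf_rounds=2,
                                        seed=11)


def rref_kernel(H: np.ndarray) -> np.ndarray:
    """Independent kernel computation by Gauss-Jordan elimination.

    Returns a (4, k) basis of {alpha : H alpha = 0} derived from the
    reduced row echelon form, with no reliance on the package's SVD route.
    """
    A = np.array(H, dtype=float)
    m, n = A.shape
    pivots = []
    row = 0
    for col in range(n):
        if row >= m:
            break
        p = row + int(np.argmax(np.abs(A[row:, col])))
        if abs(A[p, col]) < 1e-12:
            continue
        A[[row, p]] = A[[p, row]]
        A[row] = A[row] / A[row, col]
        for r in range(m):
            if r != row:
                A[r] -= A[r, col] * A[row]
        pivots.append(col)
        row += 1
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for f in free:
        v = np.zeros(n)
        v[f] = 1.0
        for r, c in enumerate(pivots):
            v[c] = -A[r, f]
        basis.append(v)
    return np.array(basis).T
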