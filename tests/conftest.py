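"""Shared fixtures: toy system operators and small phantom/geometry setups."""

import numpy as np
import pytest
import scipy.sparse as sp

from iterfbp.core import Geometry, SystemMatrix, parallel_geometry
from iterfbp.phantoms import make_disk_phantom


def toy_system(shape: tuple[int, int], seed: int, dup_rows: int = 0) -> SystemMatrix:
    """A well-conditioned non-negative toy operator wrapped as a SystemMatrix.

    Identity plus 0.15*|noise|; ``dup_rows`` duplicates the first rows onto
    the last ones, producing a rank-deficient operator.
    """
    rng = np.random.default_rng(seed)
    A = np.eye(*shape) + 0.15 * np.abs(rng.standard_normal(shape))
    if dup_rows:
        A[-dup_rows:, :] = A[:dup_rows, :]
    geom = Geometry(angles=np.array([0.0]), num_bins=shape[0], bin_spacing=1000.0)
    return SystemMatrix(
        geometry=geom, height=1, width=shape[1], pixel_size=1.0, entries=sp.csr_matrix(A)
    )


def near_optimal_theta(E: SystemMatrix) -> float:
    """2 / (lam_max + lam_min) over the nonzero spectrum of E E^T — the
    fastest-contracting relaxation, strictly inside (0, 2/lam_1)."""
    A = E.toarray()
    lams = np.linalg.eigvalsh(A @ A.T)
    nz = lams[lams > lams.max() * 1e-10]
    return 2.0 / (nz.max() + nz.min())


@pytest.fixture
def small_geometry() -> Geometry:
    return parallel_geometry(12, 8, 8)


@pytest.fixture
def disk64():
    return make_disk_phantom(64, 64, 0.25, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
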