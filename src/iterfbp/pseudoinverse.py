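"""First-order iterative approximation of the Moore-Penrose generalized
inverse of the projection operator E.

Starting from P_0 = theta * E^T with the relaxation theta inside the spectral
interval (0, 2 / lambda_1(E E^T)), the sequence

    P_{K+1} = P_K + P_0 - P_0 E P_K

converges to the generalized inverse E+.  The residual C_K = Pi_range(E) -
E P_K (Pi the orthogonal projector onto range(E)) contracts geometrically,
||C_{K+1}|| <= ||C_0|| ||C_K||, whenever ||C_0|| < 1.  Applying the whole
recursion to a projection vector u turns the matrix iteration into an image
iteration, which is the form the production reconstruction loop
(:mod:`iterfbp.iterative`) implements with FBP standing in for P_0.

The dense-matrix path here is deliberately restricted to small systems
(h*w <= 1024): it exists to make the algebra testable against dense oracles,
not to reconstruct full-size images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ImageGrid, Sinogram, SystemMatrix

__all__ = [
    "PseudoInverseState",
    "SolveResult",
    "theta_bound",
    "select_theta",
    "pseudoinverse_init",
    "pseudoinverse_step",
    "pseudoinverse_solve",
]

_MAX_DENSE_PIXELS = 1024


@dataclass
class PseudoInverseState:
    """One iterate of the generalized-inverse recursion.

    ``P`` is the current (h*w) x (X*Y) dense approximation P_K, ``k`` the
    iteration index, ``residual_norm`` the spectral norm of
    C_K = Pi_range(E) - E P_K.
    """

    P: np.ndarray
    k: int
    residual_norm: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("iteration index must be non-negative")
        # +inf is the sentinel for numerically detected divergence; NaN is a bug
        if np.isnan(self.residual_norm) or self.residual_norm < 0:
            raise ValueError("residual norm must be non-negative and not NaN")


@dataclass
class SolveResult:
    """Outcome of :func:`pseudoinverse_solve`."""

    image: ImageGrid
    iterations: int
    converged: bool
    residual_norm: float
    final_delta: float


def theta_bound(E: SystemMatrix, tol: float = 1e-8, max_iters: int = 50000) -> float:
    """Upper end of the admissible relaxation interval: 2 / lambda_1(E E^T).

    lambda_1 is the largest eigenvalue of E E^T, computed by power iteration
    to ``tol`` relative accuracy.  Valid theta lie strictly inside
    (0, theta_bound).
    """
    A = E.entries
    if A.nnz == 0:
        raise ValueError("system matrix is identically zero")
    rng = np.random.default_rng(0)
    v = rng.standard_normal(A.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iters):
        w = A @ (A.T @ v)
        lam_new = float(v @ w)
        nw = np.linalg.norm(w)
        if nw == 0.0:
            # v fell in the null space of E^T; restart from a fresh vector
            v = rng.standard_normal(A.shape[0])
            v /= np.linalg.norm(v)
            continue
        v = w / nw
        if abs(lam_new - lam) <= tol * abs(lam_new):
            lam = lam_new
            break
        lam = lam_new
    return 2.0 / lam


def select_theta(height: int, width: int, X: int, Y: int, E: SystemMatrix) -> float:
    """Dimension-based relaxation rule, clamped inside the spectral interval.

    For an underdetermined image (h*w < Y*X) the nominal choice is theta = 1;
    otherwise theta = 2^(-(h*w)/(Y*X)).  Either value is capped at 0.99 times
    :func:`theta_bound` so the returned theta always lies strictly inside
    (0, theta_bound).
    """
    if height < 1 or width < 1 or X < 1 or Y < 1:
        raise ValueError("dimensions must be positive")
    cap = 0.99 * theta_bound(E)
    hw, yx = height * width, Y * X
    nominal = 1.0 if hw < yx else 2.0 ** (-hw / yx)
    return min(nominal, cap)


def _range_projector(dense: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto range(E), via SVD with a rank tolerance."""
    u, s, _ = np.linalg.svd(dense, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.zeros((dense.shape[0], dense.shape[0]))
    rank = int(np.sum(s > s[0] * max(dense.shape) * np.finfo(float).eps))
    ur = u[:, :rank]
    return ur @ ur.T


def _residual_norm(dense: np.ndarray, P: np.ndarray, projector: np.ndarray) -> float:
    return float(np.linalg.norm(projector - dense @ P, 2))


def pseudoinverse_init(
    E: SystemMatrix, theta: float, enforce_bound: bool = True
) -> PseudoInverseState:
    """Initial iterate P_0 = theta * E^T with its residual norm.

    With ``enforce_bound`` (default) theta must lie strictly inside
    (0, theta_bound(E)); disabling the check permits deliberately
    out-of-bound theta for divergence experiments.
    """
    if E.shape[1] > _MAX_DENSE_PIXELS:
        raise ValueError(
            f"dense pseudo-inverse path is limited to {_MAX_DENSE_PIXELS} pixels; "
            "use the image-domain reconstruction for larger grids"
        )
    if enforce_bound:
        bound = theta_bound(E)
        if not 0.0 < theta < bound:
            raise ValueError(f"theta={theta} outside the open interval (0, {bound})")
    elif theta <= 0.0:
        raise ValueError("theta must be positive")
    dense = E.toarray()
    P0 = theta * dense.T
    projector = _range_projector(dense)
    return PseudoInverseState(P=P0, k=0, residual_norm=_residual_norm(dense, P0, projector))


def pseudoinverse_step(
    state: PseudoInverseState, E: SystemMatrix, P0: np.ndarray
) -> PseudoInverseState:
    """One recursion step P_{K+1} = P_K + P_0 - P_0 E P_K."""
    dense = E.toarray()
    if state.P.shape != P0.shape or state.P.shape != (dense.shape[1], dense.shape[0]):
        raise ValueError(
            f"shape mismatch: P {state.P.shape}, P0 {P0.shape}, E {dense.shape}"
        )
    P_next = state.P + P0 - P0 @ (dense @ state.P)
    residual = _range_projector(dense) - dense @ P_next
    if np.all(np.isfinite(residual)):
        res = float(np.linalg.norm(residual, 2))
    else:
        res = float("inf")
    return PseudoInverseState(P=P_next, k=state.k + 1, residual_norm=res)


def pseudoinverse_solve(
    E: SystemMatrix,
    U: Sinogram,
    theta: float | None = None,
    phi: float | None = None,
    max_iters: int = 50,
) -> SolveResult:
    """Reconstruct by explicitly iterating the generalized inverse: x = P_K u.

    Stops when ||P_{K+1} u - P_K u||_2 <= phi (default 1e-4 ||P_0 u||) or at
    ``max_iters``; non-convergence is reported via ``converged=False`` and a
    warning, with the last iterate still returned.  Small systems only
    (h*w <= 1024) — P_K is dense.
    """
    if theta is None:
        theta = select_theta(
            E.height, E.width, E.geometry.num_angles, E.geometry.num_bins, E
        )
    state = pseudoinverse_init(E, theta)
    P0 = state.P.copy()
    u = U.flatten()
    x = state.P @ u
    if phi is None:
        phi = 1e-4 * float(np.linalg.norm(x))
    converged = False
    delta = 0.0
    for _ in range(max_iters):
        state = pseudoinverse_step(state, E, P0)
        x_next = state.P @ u
        if not np.all(np.isfinite(x_next)):
            warnings.warn(
                f"pseudo-inverse iteration diverged at step {state.k}; "
                "returning the last finite iterate",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        delta = float(np.linalg.norm(x_next - x))
        x = x_next
        if delta <= phi:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"pseudo-inverse solve did not converge in {max_iters} iterations "
            f"(last delta {delta:.3e}, residual norm {state.residual_norm:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    image = ImageGrid(values=x.reshape(E.height, E.width), pixel_size=E.pixel_size)
    return SolveResult(
        image=image,
        iterations=state.k,
        converged=converged,
        residual_norm=state.residual_norm,
        final_delta=delta,
    )
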