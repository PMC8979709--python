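"""Forward and back projection under parallel-beam geometry.

All three entry points — :func:`project`, :func:`backproject` and
:func:`build_system_matrix` — share one Siddon-style ray tracer that computes
exact ray/pixel intersection lengths, so the matrix-free operators agree with
the explicit sparse matrix to rounding error and ``backproject`` is the exact
adjoint (transpose) of ``project`` under the same discretization.

Coordinate conventions: the image is centred on the rotation axis, pixel
centres at half-integer offsets from the grid centre; column index j grows
with +x, row index i grows with +y.  A ray at angle ``a`` with detector
offset ``t`` passes through ``(t cos a, t sin a)`` with direction
``(-sin a, cos a)`` — at angle 0 the rays are vertical, so a sinogram row at
angle 0 holds column sums times the pixel size.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .core import Geometry, ImageGrid, Sinogram, SystemMatrix

__all__ = ["project", "backproject", "build_system_matrix"]

_EPS = 1e-12


def _check_coverage(geometry: Geometry, height: int, width: int, pixel_size: float) -> None:
    if not geometry.covers(height, width, pixel_size):
        diag = pixel_size * float(np.hypot(height, width))
        raise ValueError(
            "detector does not cover the image diagonal: "
            f"{geometry.num_bins} bins * {geometry.bin_spacing} mm < {diag:.3f} mm"
        )


def _ray_segments(
    angle: float, offsets: np.ndarray, height: int, width: int, pixel_size: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trace every detector ray of one angle through the pixel grid.

    Returns ``(bins, pixels, lengths)`` flat arrays: for each traversed
    segment the detector bin index, the flat (row-major) pixel index and the
    intersection length in mm.
    """
    s = pixel_size
    dx, dy = -np.sin(angle), np.cos(angle)
    p0x = offsets * np.cos(angle)
    p0y = offsets * np.sin(angle)
    half_w = 0.5 * width * s
    half_h = 0.5 * height * s
    n = offsets.size

    # slab clipping of the ray parameter to the image bounding box
    amin = np.full(n, -np.inf)
    amax = np.full(n, np.inf)
    for d, p0, half in ((dx, p0x, half_w), (dy, p0y, half_h)):
        if abs(d) > _EPS:
            a1 = (-half - p0) / d
            a2 = (half - p0) / d
            amin = np.maximum(amin, np.minimum(a1, a2))
            amax = np.minimum(amax, np.maximum(a1, a2))
        else:
            outside = (p0 <= -half) | (p0 >= half)
            amax = np.where(outside, -np.inf, amax)
    miss = ~(amax > amin)
    amin = np.where(miss, 0.0, amin)
    amax = np.where(miss, 0.0, amax)

    parts = [amin[:, None], amax[:, None]]
    if abs(dx) > _EPS:
        x_edges = (np.arange(width + 1) - 0.5 * width) * s
        parts.append((x_edges[None, :] - p0x[:, None]) / dx)
    if abs(dy) > _EPS:
        y_edges = (np.arange(height + 1) - 0.5 * height) * s
        parts.append((y_edges[None, :] - p0y[:, None]) / dy)
    alphas = np.concatenate(parts, axis=1)
    np.clip(alphas, amin[:, None], amax[:, None], out=alphas)
    alphas.sort(axis=1)

    lengths = np.diff(alphas, axis=1)
    mids = 0.5 * (alphas[:, :-1] + alphas[:, 1:])
    xm = p0x[:, None] + mids * dx
    ym = p0y[:, None] + mids * dy
    ix = np.floor((xm + half_w) / s).astype(np.int64)
    iy = np.floor((ym + half_h) / s).astype(np.int64)
    valid = (
        (lengths > _EPS * s)
        & (ix >= 0)
        & (ix < width)
        & (iy >= 0)
        & (iy < height)
    )
    bins = np.broadcast_to(np.arange(n)[:, None], lengths.shape)
    return bins[valid], (iy * width + ix)[valid], lengths[valid]


def project(image: ImageGrid, geometry: Geometry) -> Sinogram:
    """Line-integral forward projection ``u = E r`` (matrix-free).

    Linear in the image; agrees with ``build_system_matrix(...).entries @
    image.flatten()`` to rounding error because both use the same ray tracer.
    """
    _check_coverage(geometry, image.height, image.width, image.pixel_size)
    flat = image.flatten()
    offsets = geometry.bin_offsets
    out = np.zeros((geometry.num_angles, geometry.num_bins))
    for a, angle in enumerate(geometry.angles):
        bins, pix, lengths = _ray_segments(
            angle, offsets, image.height, image.width, image.pixel_size
        )
        np.add.at(out[a], bins, lengths * flat[pix])
    return Sinogram(geometry=geometry, values=out)


def backproject(
    sino: Sinogram, height: int, width: int, pixel_size: float
) -> ImageGrid:
    """Exact adjoint of :func:`project`: ``r = E^T u``, reshaped to the grid.

    This is the unfiltered, length-weighted backprojection; filtered back
    projection composes it with :func:`iterfbp.fbp.filter_sinogram`.
    """
    _check_coverage(sino.geometry, height, width, pixel_size)
    offsets = sino.geometry.bin_offsets
    flat = np.zeros(height * width)
    for a, angle in enumerate(sino.geometry.angles):
        bins, pix, lengths = _ray_segments(angle, offsets, height, width, pixel_size)
        np.add.at(flat, pix, lengths * sino.values[a, bins])
    return ImageGrid(values=flat.reshape(height, width), pixel_size=pixel_size)


def build_system_matrix(
    geometry: Geometry, height: int, width: int, pixel_size: float
) -> SystemMatrix:
    """Assemble the explicit sparse projection operator E.

    Row order is angle-major then bin; column order is row-major pixels.
    Intended for small grids (testing the iterative algebra); the matrix-free
    operators are the production path.
    """
    _check_coverage(geometry, height, width, pixel_size)
    offsets = geometry.bin_offsets
    rows, cols, data = [], [], []
    for a, angle in enumerate(geometry.angles):
        bins, pix, lengths = _ray_segments(angle, offsets, height, width, pixel_size)
        rows.append(a * geometry.num_bins + bins)
        cols.append(pix)
        data.append(lengths)
    entries = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geometry.num_angles * geometry.num_bins, height * width),
    )
    return SystemMatrix(
        geometry=geometry,
        height=height,
        width=width,
        pixel_size=pixel_size,
        entries=entries,
    )
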