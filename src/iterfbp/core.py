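"""Shared containers: attenuation images, acquisition geometry, sinograms.

The discrete forward model is ``u = E r`` where ``r`` is the image flattened
row-major (length h*w), ``u`` the sinogram flattened angle-major (length X*Y)
and ``E`` the sparse matrix of ray/pixel intersection lengths.  All physical
lengths are in millimetres; attenuation values are dimensionless (phantom
convention, roughly [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["ImageGrid", "Geometry", "Sinogram", "SystemMatrix", "parallel_geometry"]


@dataclass
class ImageGrid:
    """A 2-D attenuation image on a square-pixel grid.

    Parameters
    ----------
    values : (height, width) array of finite floats
        Linear-attenuation values.  Phantom generators keep these in [0, 1];
        reconstructions may leave the range (the iterative update is signed).
    pixel_size : float
        Edge length of one pixel in mm.
    """

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("image dimensions must be at least 1x1")
        if not float(self.pixel_size) > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        self.pixel_size = float(self.pixel_size)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def flatten(self) -> np.ndarray:
        """Row-major pixel vector (the ``r`` of ``u = E r``)."""
        return self.values.ravel()


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry.

    ``angles`` are the X projection angles in radians, strictly increasing
    within [0, pi).  The Y detector bins are centred on the rotation axis
    with spacing ``bin_spacing`` (mm); one ray passes through each bin
    centre, perpendicular to the detector.
    """

    angles: np.ndarray
    num_bins: int
    bin_spacing: float = 1.0

    def __post_init__(self) -> None:
        angles = np.atleast_1d(np.asarray(self.angles, dtype=np.float64))
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "num_bins", int(self.num_bins))
        object.__setattr__(self, "bin_spacing", float(self.bin_spacing))
        if angles.size < 1:
            raise ValueError("need at least one projection angle")
        if np.any(angles < 0.0) or np.any(angles >= np.pi):
            raise ValueError("angles must lie in [0, pi)")
        if angles.size > 1 and np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.num_bins < 1:
            raise ValueError("need at least one detector bin")
        if self.bin_spacing <= 0:
            raise ValueError("bin_spacing must be positive")

    @property
    def num_angles(self) -> int:
        return int(self.angles.size)

    @property
    def bin_offsets(self) -> np.ndarray:
        """Signed detector offsets (mm) of the bin centres."""
        return (np.arange(self.num_bins) - (self.num_bins - 1) / 2.0) * self.bin_spacing

    def covers(self, height: int, width: int, pixel_size: float) -> bool:
        """Whether the detector spans the image diagonal."""
        diag = pixel_size * float(np.hypot(height, width))
        return self.num_bins * self.bin_spacing >= diag - 1e-9


def parallel_geometry(
    num_angles: int,
    height: int,
    width: int | None = None,
    pixel_size: float = 1.0,
    num_bins: int | None = None,
    bin_spacing: float | None = None,
) -> Geometry:
    """Default geometry: X angles uniform in [0, pi), detector covering the diagonal.

    ``num_bins`` defaults to ``ceil(sqrt(2) * max(h, w))`` with bin spacing equal
    to the pixel size, which always spans the image diagonal.
    """
    if width is None:
        width = height
    if bin_spacing is None:
        bin_spacing = pixel_size
    if num_bins is None:
        num_bins = int(np.ceil(np.sqrt(2.0) * max(height, width)))
        # guard against rounding for strongly anisotropic grids
        while num_bins * bin_spacing < pixel_size * np.hypot(height, width):
            num_bins += 1
    angles = np.arange(num_angles) * (np.pi / num_angles)
    return Geometry(angles=angles, num_bins=num_bins, bin_spacing=bin_spacing)


@dataclass
class Sinogram:
    """Projection data: one row of ``geometry.num_bins`` line integrals per angle.

    Values are line integrals of attenuation, units attenuation*mm.
    """

    geometry: Geometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.num_angles, self.geometry.num_bins)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def num_angles(self) -> int:
        return self.geometry.num_angles

    @property
    def num_bins(self) -> int:
        return self.geometry.num_bins

    def flatten(self) -> np.ndarray:
        """Angle-major ray vector (the ``u`` of ``u = E r``)."""
        return self.values.ravel()


@dataclass
class SystemMatrix:
    """Explicit sparse projection operator E for small grids.

    Rows are rays ordered angle-major then bin; columns are pixels ordered
    row-major.  Entry (ray, pixel) is the intersection length in mm of that
    ray with that pixel, so ``E @ image.flatten()`` is exactly the sinogram.
    """

    geometry: Geometry
    height: int
    width: int
    pixel_size: float
    entries: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        expected = (self.geometry.num_angles * self.geometry.num_bins, self.height * self.width)
        if self.entries.shape != expected:
            raise ValueError(f"system matrix shape {self.entries.shape}, expected {expected}")
        if self.entries.nnz and self.entries.data.min() < 0:
            raise ValueError("system matrix entries must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def toarray(self) -> np.ndarray:
        return self.entries.toarray()
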