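"""Deterministic 2-D phantoms: uniform disks, Shepp-Logan-style ellipse
composites, and "lesion" phantoms with a necrotic focus and a rim-enhanced
pseudocyst, echoing the morphology of severe-pancreatitis CT findings.

Ellipses are specified in a normalized frame: the square [-1, 1] x [-1, 1]
mapped onto the pixel grid, origin at the grid centre.  A pixel belongs to an
ellipse iff its centre does (pixel centres at half-integer offsets; no
anti-aliasing), so membership is exactly checkable against the analytic
inequality.  Summed ellipse values are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImageGrid

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "make_disk_phantom",
    "make_phantom",
    "shepp_logan_ellipses",
]


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse in the normalized [-1, 1]^2 frame.

    ``value`` is added inside the ellipse (may be negative for cavities);
    ``rotation_deg`` rotates the axes counter-clockwise.
    """

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation_deg: float = 0.0
    value: float = 1.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.center_x <= 1.0 and -1.0 <= self.center_y <= 1.0):
            raise ValueError("ellipse centre must lie in the normalized square [-1, 1]^2")
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


# Standard head-phantom ellipse table (modified intensities so the composite
# stays in [0, 1]): (cx, cy, a, b, rotation_deg, additive value).
_SHEPP_LOGAN = [
    (0.0, 0.0, 0.69, 0.92, 90.0, 1.0),
    (0.0, -0.0184, 0.6624, 0.874, 90.0, -0.8),
    (0.22, 0.0, 0.11, 0.31, 72.0, -0.2),
    (-0.22, 0.0, 0.16, 0.41, 108.0, -0.2),
    (0.0, 0.35, 0.21, 0.25, 90.0, 0.1),
    (0.0, 0.1, 0.046, 0.046, 0.0, 0.1),
    (0.0, -0.1, 0.046, 0.046, 0.0, 0.1),
    (-0.08, -0.605, 0.046, 0.023, 0.0, 0.1),
    (0.0, -0.605, 0.023, 0.023, 0.0, 0.1),
    (0.06, -0.605, 0.023, 0.046, 0.0, 0.1),
]


def shepp_logan_ellipses() -> list[Ellipse]:
    """The classic ten-ellipse head phantom with contrast-adjusted values."""
    return [Ellipse(*row[:4], rotation_deg=row[4], value=row[5]) for row in _SHEPP_LOGAN]


@dataclass
class PhantomSpec:
    """Recipe for a phantom: a kind, an ellipse list and a seed.

    For ``kind="lesion"`` an empty ellipse list is filled in deterministically
    from ``seed``: a soft-tissue background ellipse, at least one low-value
    interior region (necrotic-focus analogue) and one ring-enhanced region
    (pseudocyst analogue, a bright rim around a dark core).
    """

    kind: str = "lesion"
    ellipses: list[Ellipse] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"disk", "shepp_logan", "lesion"}:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        self.ellipses = [e if isinstance(e, Ellipse) else Ellipse(*e) for e in self.ellipses]


def _lesion_ellipses(rng: np.random.Generator) -> list[Ellipse]:
    """Seeded organ-with-lesions layout in the normalized frame."""
    ellipses = [Ellipse(0.0, 0.0, 0.85, 0.7, rng.uniform(-15, 15), 0.5)]
    # necrotic focus: hypodense interior region
    cx, cy = rng.uniform(-0.3, 0.1), rng.uniform(-0.25, 0.25)
    ellipses.append(Ellipse(cx, cy, rng.uniform(0.1, 0.18), rng.uniform(0.08, 0.14),
                            rng.uniform(0, 180), -0.35))
    # pseudocyst: bright rim (outer ellipse up, inner core back down)
    cx, cy = rng.uniform(0.25, 0.45), rng.uniform(-0.2, 0.2)
    outer_a, outer_b = rng.uniform(0.16, 0.22), rng.uniform(0.13, 0.18)
    rot = rng.uniform(0, 180)
    ellipses.append(Ellipse(cx, cy, outer_a, outer_b, rot, 0.45))
    ellipses.append(Ellipse(cx, cy, 0.7 * outer_a, 0.7 * outer_b, rot, -0.55))
    return ellipses


def _pixel_centers(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (x, y) coordinates of every pixel centre."""
    x = -1.0 + 2.0 * (np.arange(width) + 0.5) / width
    y = -1.0 + 2.0 * (np.arange(height) + 0.5) / height
    return np.meshgrid(x, y)


def ellipse_mask(ellipse: Ellipse, height: int, width: int) -> np.ndarray:
    """Boolean pixel-centre membership for one ellipse."""
    xx, yy = _pixel_centers(height, width)
    phi = np.deg2rad(ellipse.rotation_deg)
    dx = xx - ellipse.center_x
    dy = yy - ellipse.center_y
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    return (xr / ellipse.semi_axis_a) ** 2 + (yr / ellipse.semi_axis_b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec, height: int, width: int, pixel_size: float = 1.0) -> ImageGrid:
    """Render a PhantomSpec: sum of ellipse indicator values, clipped to [0, 1].

    Deterministic for identical (spec, dims); ``kind="shepp_logan"`` and
    ``kind="disk"`` require a non-empty ellipse list (use
    :func:`shepp_logan_ellipses` for the standard head layout).
    """
    if height < 1 or width < 1:
        raise ValueError("phantom dimensions must be at least 1x1")
    ellipses = list(spec.ellipses)
    if not ellipses:
        if spec.kind == "lesion":
            ellipses = _lesion_ellipses(np.random.default_rng(spec.seed))
        else:
            raise ValueError(f"kind {spec.kind!r} requires a non-empty ellipse list")
    values = np.zeros((height, width))
    for e in ellipses:
        values[ellipse_mask(e, height, width)] += e.value
    np.clip(values, 0.0, 1.0, out=values)
    return ImageGrid(values=values, pixel_size=pixel_size)


def make_disk_phantom(
    height: int,
    width: int,
    radius_fraction: float,
    value: float,
    pixel_size: float = 1.0,
) -> ImageGrid:
    """Uniform centred disk of radius ``radius_fraction * min(height, width)`` px.

    ``value`` fills pixels whose centre lies inside the disk; outside is 0.
    """
    if height < 1 or width < 1:
        raise ValueError("phantom dimensions must be at least 1x1")
    if not 0.0 < radius_fraction <= 0.5:
        raise ValueError(f"radius_fraction must be in (0, 0.5], got {radius_fraction}")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"value must be in [0, 1], got {value}")
    radius = radius_fraction * min(height, width)
    jj, ii = np.meshgrid(np.arange(width) + 0.5, np.arange(height) + 0.5)
    inside = (jj - width / 2.0) ** 2 + (ii - height / 2.0) ** 2 <= radius**2
    values = np.where(inside, float(value), 0.0)
    return ImageGrid(values=values, pixel_size=pixel_size)
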