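"""Image-quality metrics: MSE, ROI noise, SNR and contrast.

MSE is the mean squared pixel difference over the full grid,
MSE = (1/M) sum_i (y_i - yhat_i)^2 with M the pixel count, y the reference
and yhat the estimate.  Noise is the sample standard deviation inside a
declared uniform ROI; SNR is signal-ROI mean over background-ROI standard
deviation; contrast is the absolute difference of two ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import ImageGrid

__all__ = ["ROI", "MetricReport", "mse", "noise_std", "snr", "contrast", "evaluate"]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open pixel coordinates."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI must be at least 1x1")

    def extract(self, image: ImageGrid) -> np.ndarray:
        if self.top + self.height > image.height or self.left + self.width > image.width:
            raise ValueError(
                f"ROI {self} extends outside the {image.height}x{image.width} image"
            )
        return image.values[self.top : self.top + self.height, self.left : self.left + self.width]

    @property
    def num_pixels(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class MetricReport:
    """The four image-quality numbers for one reconstruction."""

    mse: float
    noise_std: float
    snr: float
    contrast: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def mse(reference: ImageGrid, estimate: ImageGrid) -> float:
    """Mean squared error over all pixels; symmetric, zero iff identical."""
    if reference.shape != estimate.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {estimate.shape}")
    return float(np.mean((reference.values - estimate.values) ** 2))


def noise_std(image: ImageGrid, roi: ROI) -> float:
    """Sample standard deviation (ddof=1) of the pixels in a uniform ROI."""
    if roi.num_pixels < 2:
        raise ValueError("noise ROI needs at least 2 pixels")
    return float(np.std(roi.extract(image), ddof=1))


def snr(image: ImageGrid, signal_roi: ROI, background_roi: ROI) -> float:
    """Signal-ROI mean divided by background-ROI standard deviation."""
    sigma = noise_std(image, background_roi)
    if sigma == 0.0:
        raise ValueError(f"background ROI {background_roi} has zero standard deviation")
    return float(np.mean(signal_roi.extract(image))) / sigma


def contrast(image: ImageGrid, roi_a: ROI, roi_b: ROI) -> float:
    """Absolute difference of the two ROI means; symmetric, non-negative."""
    return float(abs(np.mean(roi_a.extract(image)) - np.mean(roi_b.extract(image))))


def evaluate(
    reference: ImageGrid,
    estimate: ImageGrid,
    uniform_roi: ROI,
    background_roi: ROI,
    contrast_roi: ROI | None = None,
) -> MetricReport:
    """Bundle the four metrics for one (reference, estimate) pair.

    ``contrast`` compares the uniform ROI against ``contrast_roi`` when
    given, else against the background ROI.
    """
    other = contrast_roi if contrast_roi is not None else background_roi
    return MetricReport(
        mse=mse(reference, estimate),
        noise_std=noise_std(estimate, uniform_roi),
        snr=snr(estimate, uniform_roi, background_roi),
        contrast=contrast(estimate, uniform_roi, other),
    )
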