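"""Low-dose acquisition simulator and the dose-ladder experiment.

Dose reduction is modelled as Poisson thinning of a Beer-Lambert photon
count: a detector bin with noiseless line integral p receives
N ~ Poisson(I0 * d * exp(-p)) photons at dose fraction d, and the measured
integral is phat = -ln(N / (I0 * d)).  Zero counts are floored to one photon
before the log, the standard guard that keeps phat finite.  By the delta
method, var(phat) ~= exp(p) / (I0 * d): halving the dose doubles the
sinogram-domain noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Geometry, ImageGrid, Sinogram
from .fbp import fbp_reconstruct
from .iterative import ReconConfig, ifbp_reconstruct
from .metrics import ROI, mse, noise_std, snr
from .projector import project

__all__ = ["NoiseModel", "simulate_low_dose", "dose_ladder", "default_rois"]


@dataclass(frozen=True)
class NoiseModel:
    """Photon-statistics model: full-dose flux per bin, dose fraction, seed."""

    incident_photons: float = 1e5
    dose_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.incident_photons < 1:
            raise ValueError(f"incident_photons must be >= 1, got {self.incident_photons}")
        if not 0.0 < self.dose_fraction <= 1.0:
            raise ValueError(f"dose_fraction must be in (0, 1], got {self.dose_fraction}")


def simulate_low_dose(sino: Sinogram, model: NoiseModel) -> Sinogram:
    """Inject Poisson photon noise into a noiseless sinogram.

    Requires non-negative line integrals; fully seeded and reproducible.
    """
    p = sino.values
    if np.any(p < 0):
        raise ValueError("line integrals must be non-negative for photon noise")
    flux = model.incident_photons * model.dose_fraction
    rng = np.random.default_rng(model.seed)
    counts = rng.poisson(flux * np.exp(-p)).astype(np.float64)
    np.maximum(counts, 1.0, out=counts)
    return Sinogram(geometry=sino.geometry, values=-np.log(counts / flux))


def default_rois(height: int, width: int) -> dict[str, ROI]:
    """Default measurement regions for centred-disk-style phantoms.

    ``uniform`` sits at the centre (inside the object, used for noise and as
    the SNR signal region); ``background`` sits near the corner, in air but
    inside the reconstructed field of view.
    """
    side = max(2, height // 4)
    corner = max(2, height // 8)
    margin = max(1, height // 16)
    return {
        "uniform": ROI((height - side) // 2, (width - side) // 2, side, side),
        "background": ROI(margin, margin, corner, corner),
    }


def dose_ladder(
    image: ImageGrid,
    geometry: Geometry,
    fractions: list[float],
    incident_photons: float = 1e5,
    seed: int = 0,
    config: ReconConfig | None = None,
    rois: dict[str, ROI] | None = None,
) -> pd.DataFrame:
    """Reconstruct one phantom at several dose fractions with FBP and
    iterative FBP, and tabulate image-quality metrics.

    At each dose both methods see the *same* noisy sinogram (paired
    comparison); per-dose seeds are derived from ``seed`` by fixed offsets.
    Returns one row per (dose_fraction, method) with columns
    (dose_fraction, method, noise_std, mse, snr, sino_noise_var).
    """
    if not fractions:
        raise ValueError("need at least one dose fraction")
    if any(not 0.0 < d <= 1.0 for d in fractions):
        raise ValueError("dose fractions must lie in (0, 1]")
    if config is None:
        config = ReconConfig()
    if rois is None:
        rois = default_rois(image.height, image.width)

    clean = project(image, geometry)
    rows = []
    for i, d in enumerate(fractions):
        model = NoiseModel(
            incident_photons=incident_photons, dose_fraction=d, seed=seed + 101 * i
        )
        noisy = simulate_low_dose(clean, model)
        sino_var = float(np.mean((noisy.values - clean.values) ** 2))
        fbp_img = fbp_reconstruct(
            noisy, image.height, image.width, image.pixel_size, config.filter
        )
        ifbp_img, _ = ifbp_reconstruct(
            noisy, image.height, image.width, image.pixel_size, config
        )
        for method, recon in (("fbp", fbp_img), ("ifbp", ifbp_img)):
            rows.append(
                {
                    "dose_fraction": d,
                    "method": method,
                    "noise_std": noise_std(recon, rois["uniform"]),
                    "mse": mse(image, recon),
                    "snr": snr(recon, rois["uniform"], rois["background"]),
                    "sino_noise_var": sino_var,
                }
            )
    return pd.DataFrame(rows)
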