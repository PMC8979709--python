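"""End-to-end simulated acquisition pipeline:
phantom -> project -> (noise) -> FBP + iterative FBP -> metrics.

Every stage output is written to disk and listed in a JSON manifest together
with the per-stage seeds and a hash of the configuration, so a run is fully
reproducible and idempotent for a fixed seed.  One global seed fans out to
per-stage seeds by fixed offsets (phantom: +7, noise: +101) so stages can be
re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import parallel_geometry
from .dose import NoiseModel, default_rois, simulate_low_dose
from .fbp import fbp_reconstruct
from .iterative import ReconConfig, ifbp_reconstruct
from .io import recon_config_from_dict, write_image, write_sinogram
from .metrics import ROI, evaluate
from .phantoms import PhantomSpec, make_phantom, shepp_logan_ellipses
from .projector import project

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

_PHANTOM_SEED_OFFSET = 7
_NOISE_SEED_OFFSET = 101


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunConfig:
    """Configuration of one simulated acquisition + reconstruction run."""

    size: int = 128
    pixel_size: float = 1.0
    phantom_kind: str = "lesion"
    num_angles: int = 180
    noise: NoiseModel | None = None
    recon: ReconConfig = field(default_factory=ReconConfig)
    rois: dict[str, ROI] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("size", "num_angles"):
            if key not in data:
                raise ValueError(f"run config is missing required field {key!r}")
        noise = None
        if data.get("noise"):
            noise = NoiseModel(
                incident_photons=float(data["noise"].get("incident_photons", 1e5)),
                dose_fraction=float(data["noise"].get("dose_fraction", 1.0)),
                seed=int(data["noise"].get("seed", 0)),
            )
        rois = None
        if data.get("rois"):
            rois = {name: ROI(**spec) for name, spec in data["rois"].items()}
        return cls(
            size=int(data["size"]),
            pixel_size=float(data.get("pixel_size", 1.0)),
            phantom_kind=data.get("phantom_kind", "lesion"),
            num_angles=int(data["num_angles"]),
            noise=noise,
            recon=recon_config_from_dict(data.get("recon", {})),
            rois=rois,
            seed=int(data.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "size": self.size,
            "pixel_size": self.pixel_size,
            "phantom_kind": self.phantom_kind,
            "num_angles": self.num_angles,
            "noise": None
            if self.noise is None
            else {
                "incident_photons": self.noise.incident_photons,
                "dose_fraction": self.noise.dose_fraction,
                "seed": self.noise.seed,
            },
            "recon": {
                "theta": self.recon.theta,
                "phi": self.recon.phi,
                "max_iters": self.recon.max_iters,
                "filter": {
                    "window": self.recon.filter.window,
                    "cutoff_fraction": self.recon.filter.cutoff_fraction,
                },
                "record_trace": self.recon.record_trace,
                "clamp_negative": self.recon.clamp_negative,
            },
            "seed": self.seed,
        }


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full simulated data path and return the manifest.

    Writes phantom.tif, sino.csv, optionally sino_noisy.csv, fbp.tif,
    ifbp.tif, trace.csv, metrics_fbp.json, metrics_ifbp.json and
    manifest.json under ``outdir``.  Any stage failure raises
    :class:`PipelineError` naming the stage, with the partial manifest
    attached (and written to disk).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": {
            "phantom": config.seed + _PHANTOM_SEED_OFFSET,
            "noise": config.seed + _NOISE_SEED_OFFSET,
        },
        "outputs": {},
    }

    def _fail(stage: str, exc: Exception):
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, manifest, exc) from exc

    stage = "phantom"
    try:
        logger.info("stage=%s seed=%d hash=%s", stage, config.seed, manifest["config_hash"])
        spec = PhantomSpec(
            kind=config.phantom_kind,
            ellipses=shepp_logan_ellipses() if config.phantom_kind == "shepp_logan" else [],
            seed=manifest["stage_seeds"]["phantom"],
        )
        truth = make_phantom(spec, config.size, config.size, config.pixel_size)
        write_image(outdir / "phantom.tif", truth)
        manifest["outputs"][stage] = "phantom.tif"
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail(stage, exc)

    stage = "project"
    try:
        geometry = parallel_geometry(config.num_angles, config.size, config.size, config.pixel_size)
        sino = project(truth, geometry)
        write_sinogram(outdir / "sino.csv", sino)
        manifest["outputs"][stage] = "sino.csv"
    except Exception as exc:
        _fail(stage, exc)

    measured = sino
    if config.noise is not None:
        stage = "noise"
        try:
            model = NoiseModel(
                incident_photons=config.noise.incident_photons,
                dose_fraction=config.noise.dose_fraction,
                seed=manifest["stage_seeds"]["noise"],
            )
            measured = simulate_low_dose(sino, model)
            write_sinogram(outdir / "sino_noisy.csv", measured)
            manifest["outputs"][stage] = "sino_noisy.csv"
        except Exception as exc:
            _fail(stage, exc)

    stage = "fbp"
    try:
        fbp_img = fbp_reconstruct(
            measured, config.size, config.size, config.pixel_size, config.recon.filter
        )
        write_image(outdir / "fbp.tif", fbp_img)
        manifest["outputs"][stage] = "fbp.tif"
    except Exception as exc:
        _fail(stage, exc)

    stage = "recon"
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ifbp_img, trace = ifbp_reconstruct(
                measured, config.size, config.size, config.pixel_size, config.recon, truth=truth
            )
        write_image(outdir / "ifbp.tif", ifbp_img)
        trace_lines = ["k,delta,mse"]
        for e in trace.entries:
            mse_txt = "" if e.mse_vs_truth is None else f"{e.mse_vs_truth:.17g}"
            trace_lines.append(f"{e.k},{e.delta:.17g},{mse_txt}")
        (outdir / "trace.csv").write_text("\n".join(trace_lines) + "\n")
        manifest["outputs"][stage] = "ifbp.tif"
        manifest["outputs"]["trace"] = "trace.csv"
        manifest["converged"] = trace.converged
    except Exception as exc:
        _fail(stage, exc)

    stage = "metrics"
    try:
        rois = config.rois or default_rois(config.size, config.size)
        for name, img in (("fbp", fbp_img), ("ifbp", ifbp_img)):
            report = evaluate(truth, img, rois["uniform"], rois["background"])
            out = outdir / f"metrics_{name}.json"
            out.write_text(json.dumps(report.to_dict(), indent=2))
            manifest["outputs"][f"metrics_{name}"] = out.name
    except Exception as exc:
        _fail(stage, exc)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["outputs"]["manifest"] = "manifest.json"
    return manifest
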