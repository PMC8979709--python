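"""File formats: 32-bit float TIFF images, plain-text CSV sinograms, and
YAML configuration blocks.

Sinograms are stored as text so fixtures diff cleanly under version control:
two comment headers (``# angles_deg: ...`` and ``# bin_spacing_mm: ...``)
followed by one comma-separated row of Y values per angle, printed with 17
significant digits so float64 values round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import Geometry, ImageGrid, Sinogram
from .fbp import FilterSpec
from .iterative import ReconConfig
from .phantoms import Ellipse, PhantomSpec

__all__ = [
    "read_image",
    "write_image",
    "read_sinogram",
    "write_sinogram",
    "read_geometry",
    "write_geometry",
    "read_phantom_spec",
    "write_phantom_spec",
    "recon_config_from_dict",
]


def write_image(path, image: ImageGrid) -> None:
    """Write a single-channel 32-bit float TIFF; pixel size goes into the
    resolution tags (pixels per cm) and a JSON image description."""
    res = 10.0 / image.pixel_size  # pixels per cm
    tifffile.imwrite(
        Path(path),
        image.values.astype(np.float32),
        description=json.dumps({"pixel_size_mm": image.pixel_size}),
        resolution=(res, res),
        resolutionunit="CENTIMETER",
    )


def read_image(path) -> ImageGrid:
    """Read a single-channel float TIFF back into an :class:`ImageGrid`.

    Values are bit-identical to what :func:`write_image` stored (i.e. the
    float32 cast of the original image); multi-channel input is rejected.
    """
    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        values = page.asarray()
        description = page.description
    if values.ndim != 2:
        channels = values.shape[-1] if values.ndim == 3 else values.ndim
        raise ValueError(f"expected a single-channel image, got {channels} channels")
    pixel_size = 1.0
    if description:
        try:
            pixel_size = float(json.loads(description)["pixel_size_mm"])
        except (ValueError, KeyError, TypeError):
            pass
    return ImageGrid(values=values, pixel_size=pixel_size)


def write_sinogram(path, sino: Sinogram) -> None:
    """Write the header + CSV-rows text format (17 significant digits)."""
    lines = [
        "# angles_deg: " + ",".join(f"{np.degrees(a):.17g}" for a in sino.geometry.angles),
        f"# bin_spacing_mm: {sino.geometry.bin_spacing:.17g}",
    ]
    for row in sino.values:
        lines.append(",".join(f"{v:.17g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sinogram(path) -> Sinogram:
    """Parse the sinogram text format; header/shape mismatches are errors."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"sinogram file {path} is empty or truncated")
    if not lines[0].startswith("# angles_deg:") or not lines[1].startswith("# bin_spacing_mm:"):
        raise ValueError(f"sinogram file {path} is missing its geometry header")
    angles = np.radians([float(v) for v in lines[0].split(":", 1)[1].split(",")])
    bin_spacing = float(lines[1].split(":", 1)[1])
    rows = [[float(v) for v in ln.split(",")] for ln in lines[2:]]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"ragged sinogram rows in {path}: widths {sorted(widths)}")
    values = np.array(rows)
    if values.shape[0] != angles.size:
        raise ValueError(
            f"{values.shape[0]} data rows but {angles.size} angles in {path}"
        )
    geometry = Geometry(angles=angles, num_bins=values.shape[1], bin_spacing=bin_spacing)
    return Sinogram(geometry=geometry, values=values)


def write_geometry(path, geometry: Geometry) -> None:
    data = {
        "angles_deg": [float(np.degrees(a)) for a in geometry.angles],
        "num_bins": geometry.num_bins,
        "bin_spacing_mm": geometry.bin_spacing,
    }
    Path(path).write_text(yaml.safe_dump(data))


def read_geometry(path) -> Geometry:
    data = yaml.safe_load(Path(path).read_text())
    return Geometry(
        angles=np.radians(data["angles_deg"]),
        num_bins=int(data["num_bins"]),
        bin_spacing=float(data.get("bin_spacing_mm", 1.0)),
    )


def write_phantom_spec(path, spec: PhantomSpec) -> None:
    data = {
        "kind": spec.kind,
        "seed": spec.seed,
        "ellipses": [
            [e.center_x, e.center_y, e.semi_axis_a, e.semi_axis_b, e.rotation_deg, e.value]
            for e in spec.ellipses
        ],
    }
    Path(path).write_text(yaml.safe_dump(data))


def read_phantom_spec(path) -> PhantomSpec:
    data = yaml.safe_load(Path(path).read_text())
    return PhantomSpec(
        kind=data.get("kind", "lesion"),
        ellipses=[Ellipse(*row) for row in data.get("ellipses", [])],
        seed=int(data.get("seed", 0)),
    )


def recon_config_from_dict(data: dict) -> ReconConfig:
    """Build a ReconConfig from a plain mapping (YAML/JSON friendly)."""
    filt = data.get("filter", {})
    return ReconConfig(
        theta=float(data.get("theta", 1.0)),
        phi=None if data.get("phi") in (None, "auto") else float(data["phi"]),
        max_iters=int(data.get("max_iters", 50)),
        filter=FilterSpec(
            window=filt.get("window", "hann"),
            cutoff_fraction=float(filt.get("cutoff_fraction", 1.0)),
        ),
        record_trace=bool(data.get("record_trace", True)),
        clamp_negative=bool(data.get("clamp_negative", False)),
    )
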