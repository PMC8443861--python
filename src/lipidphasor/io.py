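"""Reading and writing the pipeline's interchange formats.

Lambda stacks travel as OME-TIFF with per-channel emission wavelengths
(the lambda-stack export of commercial confocals); plain multi-page
TIFF plus an explicitly configured spectral axis is accepted as a
fallback.  Calibrated reference vertices are serialized to YAML with
their provenance, per-cell tables to CSV, and dense arrays (ground
truth, phasor and fraction fields) to compressed ``.npz`` sidecars.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .phasor import HyperspectralImage
from .spectral import SpectralAxis
from .unmix import ReferenceVertices

__all__ = [
    "write_hyperspectral",
    "read_hyperspectral",
    "save_vertices",
    "load_vertices",
    "write_label_image",
    "write_ground_truth",
]


def write_hyperspectral(path: str | Path, image: HyperspectralImage) -> None:
    """Write a lambda stack as OME-TIFF with channel emission wavelengths."""
    path = Path(path)
    wavelengths = [float(w) for w in image.axis.centers]
    tifffile.imwrite(
        path,
        np.ascontiguousarray(image.data.transpose(2, 0, 1)),
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "Channel": {
                "EmissionWavelength": wavelengths,
                "EmissionWavelengthUnit": ["nm"] * len(wavelengths),
            },
        },
    )


def _axis_from_wavelengths(centers: np.ndarray) -> SpectralAxis:
    if centers.size < 3:
        raise ValueError("need at least 3 channel wavelengths")
    steps = np.diff(centers)
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError("channel wavelengths are not uniformly spaced")
    bw = float(steps[0])
    return SpectralAxis(start=float(centers[0]) - bw / 2, bandwidth=bw, n_channels=centers.size)


def read_hyperspectral(path: str | Path, axis: SpectralAxis | None = None) -> HyperspectralImage:
    """Read a lambda stack from (OME-)TIFF.

    Channel wavelengths are parsed from OME metadata when present and
    used to build the spectral axis; otherwise ``axis`` must be given.
    The channel count of the file must match the axis in either case.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome = tf.ome_metadata if tf.is_ome else None
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D lambda stack, got shape {data.shape}")
    data = np.moveaxis(data, 0, -1)  # CYX -> YXC
    n_file = data.shape[-1]
    file_axis = None
    if ome:
        wl = [float(x) for x in re.findall(r'EmissionWavelength="([\d.eE+-]+)"', ome)]
        if wl:
            file_axis = _axis_from_wavelengths(np.asarray(wl))
    if file_axis is not None:
        if axis is not None and axis.n_channels != file_axis.n_channels:
            raise ValueError(
                f"{path}: file has {file_axis.n_channels} channels but configured axis "
                f"declares {axis.n_channels}"
            )
        axis = file_axis
    if axis is None:
        raise ValueError(f"{path}: no wavelength metadata and no spectral axis configured")
    if axis.n_channels != n_file:
        raise ValueError(
            f"{path}: file has {n_file} channels but axis declares {axis.n_channels}"
        )
    return HyperspectralImage(data=data.astype(float), axis=axis)


def save_vertices(path: str | Path, vertices: ReferenceVertices, provenance: dict | None = None) -> None:
    """Serialize reference vertices (plus calibration provenance) to YAML."""
    payload = {
        "v_polar": [float(v) for v in vertices.v_polar],
        "v_neutral": [float(v) for v in vertices.v_neutral],
        "v_egfp": [float(v) for v in vertices.v_egfp],
        "provenance": provenance or {},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_vertices(path: str | Path) -> tuple[ReferenceVertices, dict]:
    data = yaml.safe_load(Path(path).read_text())
    vertices = ReferenceVertices(
        v_polar=tuple(data["v_polar"]),
        v_neutral=tuple(data["v_neutral"]),
        v_egfp=tuple(data["v_egfp"]),
    )
    return vertices, data.get("provenance", {})


def write_label_image(path: str | Path, labels: np.ndarray) -> None:
    """Write a cell label image as 16-bit TIFF."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 cells cannot be stored as 16-bit labels")
    tifffile.imwrite(Path(path), labels.astype(np.uint16), photometric="minisblack")


def write_ground_truth(prefix: str | Path, truth) -> None:
    """Write scene ground truth: ``.npz`` arrays plus a per-cell CSV."""
    prefix = Path(prefix)
    np.savez_compressed(
        prefix.with_suffix(".npz"), fractions=truth.fractions, labels=truth.labels
    )
    truth.cell_stats.to_csv(prefix.with_suffix(".csv"), index=False)
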