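"""Spectral phasor transform and phasor-plot utilities.

Each pixel's emission spectrum I(lambda) is reduced to the first (or
n-th) harmonic of its discrete Fourier transform, normalized by total
intensity:

    G = sum_k I_k cos(2 pi n k / N) / sum_k I_k
    S = sum_k I_k sin(2 pi n k / N) / sum_k I_k

with k the channel index over N channels.  The (G, S) position encodes
the spectrum's peak (phase angle Theta) and width (modulation M):
red-shifted spectra have larger Theta, narrower bands larger M.  Because
the transform is linear in the spectrum, a mixture of emitters lands at
the intensity-weighted combination of the pure-component phasors — the
property the three-component decomposition rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .spectral import ComponentSpectrum, SpectralAxis

__all__ = [
    "HyperspectralImage",
    "PhasorParams",
    "PhasorField",
    "compute_phasor",
    "spectrum_phasor",
    "phase_modulation",
    "phasor_histogram",
    "reciprocity_select",
    "estimate_background_spectrum",
    "subtract_background",
]


@dataclass
class HyperspectralImage:
    """A lambda stack: nonnegative counts, shape (rows, cols, n_channels)."""

    data: np.ndarray
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D (rows, cols, channels), got {self.data.ndim}-D")
        if self.data.shape[2] != self.axis.n_channels:
            raise ValueError(
                f"image has {self.data.shape[2]} channels but axis declares "
                f"{self.axis.n_channels}"
            )
        if np.any(self.data < 0):
            raise ValueError("negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def total_intensity(self) -> np.ndarray:
        return self.data.sum(axis=2)


@dataclass(frozen=True)
class PhasorParams:
    """Harmonic number of the Fourier transform (default 1)."""

    harmonic: int = 1

    def __post_init__(self) -> None:
        if self.harmonic < 1:
            raise ValueError(f"harmonic must be >= 1, got {self.harmonic}")


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates with total intensity and validity flags.

    Invalid pixels (zero or sub-threshold total intensity) carry g = s = 0
    and ``valid = False``; they are excluded from all downstream statistics
    rather than propagated as NaN.
    """

    g: np.ndarray
    s: np.ndarray
    total_intensity: np.ndarray
    valid: np.ndarray
    harmonic: int = 1

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.g, self.s, self.total_intensity, self.valid)}
        if len(shapes) != 1:
            raise ValueError("g, s, total_intensity and valid must share a shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.g.shape


def _harmonic_basis(n_channels: int, harmonic: int) -> tuple[np.ndarray, np.ndarray]:
    ang = 2.0 * np.pi * harmonic * np.arange(n_channels) / n_channels
    return np.cos(ang), np.sin(ang)


def compute_phasor(
    image: HyperspectralImage,
    params: PhasorParams | None = None,
    min_intensity: float = 0.0,
) -> PhasorField:
    """Transform every pixel of a lambda stack to its (G, S) phasor.

    Parameters
    ----------
    image : HyperspectralImage
        Nonnegative lambda stack; at least one pixel must have positive
        total intensity.
    params : PhasorParams, optional
        Harmonic number (default 1).
    min_intensity : float, optional
        Pixels with total intensity <= this threshold are flagged invalid
        (background suppression; default 0 = only empty pixels excluded).

    Returns
    -------
    PhasorField
    """
    if params is None:
        params = PhasorParams()
    total = image.total_intensity
    if not np.any(total > 0):
        raise ValueError("all-zero image: no pixel with positive intensity")
    cos_k, sin_k = _harmonic_basis(image.axis.n_channels, params.harmonic)
    valid = total > max(min_intensity, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(valid, image.data @ cos_k / np.where(total > 0, total, 1.0), 0.0)
        s = np.where(valid, image.data @ sin_k / np.where(total > 0, total, 1.0), 0.0)
    return PhasorField(g=g, s=s, total_intensity=total, valid=valid, harmonic=params.harmonic)


def spectrum_phasor(
    spectrum: ComponentSpectrum | np.ndarray, harmonic: int = 1
) -> tuple[float, float]:
    """(G, S) phasor of a single 1-D spectrum (e.g. a pure component)."""
    v = spectrum.values if isinstance(spectrum, ComponentSpectrum) else np.asarray(spectrum, float)
    total = v.sum()
    if total <= 0:
        raise ValueError("spectrum has no intensity")
    cos_k, sin_k = _harmonic_basis(v.shape[0], harmonic)
    return float(v @ cos_k / total), float(v @ sin_k / total)


def phase_modulation(fld: PhasorField) -> tuple[np.ndarray, np.ndarray]:
    """Phase angle Theta in [0, 2 pi) and modulation M per pixel.

    Invalid pixels get NaN in both outputs (flagged, never raised).
    """
    theta = np.mod(np.arctan2(fld.s, fld.g), 2.0 * np.pi)
    m = np.hypot(fld.g, fld.s)
    theta = np.where(fld.valid, theta, np.nan)
    m = np.where(fld.valid, m, np.nan)
    return theta, m


def phasor_histogram(
    fld: PhasorField, bins: int = 201, intensity_weighted: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D phasor-plot density over the unit square [-1, 1]^2.

    Returns (hist, g_edges, s_edges); hist[i, j] counts pixels with G in
    bin i and S in bin j.  Unweighted counts sum to the number of valid
    pixels; with ``intensity_weighted`` each pixel contributes its total
    intensity instead.
    """
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    v = fld.valid
    if not np.any(v):
        raise ValueError("no valid pixels")
    w = fld.total_intensity[v] if intensity_weighted else None
    hist, ge, se = np.histogram2d(
        fld.g[v].ravel(), fld.s[v].ravel(), bins=bins, range=[[-1, 1], [-1, 1]], weights=w
    )
    return hist, ge, se


def estimate_background_spectrum(
    image: HyperspectralImage, threshold: float, min_pixels: int = 50
) -> np.ndarray | None:
    """Mean per-channel spectrum of sub-threshold (background) pixels.

    An additive background (autofluorescence floor, detector offset)
    drags every phasor toward the flat-spectrum origin; subtracting its
    spectrum before the transform removes that bias.  Returns None when
    fewer than ``min_pixels`` pixels fall below ``threshold`` total
    intensity (no background to estimate).
    """
    mask = image.total_intensity <= threshold
    if int(mask.sum()) < min_pixels:
        return None
    return image.data[mask].mean(axis=0)


def subtract_background(image: HyperspectralImage, spectrum: np.ndarray) -> HyperspectralImage:
    """Subtract a per-channel background spectrum, clipping at zero."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (image.axis.n_channels,):
        raise ValueError("background spectrum length does not match the axis")
    return HyperspectralImage(np.clip(image.data - spectrum, 0.0, None), image.axis)


def reciprocity_select(fld: PhasorField, region: np.ndarray) -> np.ndarray:
    """Map a phasor-space polygon back to image space.

    The reciprocity principle: selecting a region of the phasor plot
    (imaginary space) selects the originating pixels in the image (real
    space).  ``region`` is an (n, 2) array of (G, S) polygon vertices.

    Returns a boolean mask, true exactly for valid pixels whose phasor
    lies inside or on the polygon.
    """
    region = np.asarray(region, dtype=float)
    if region.ndim != 2 or region.shape[1] != 2 or region.shape[0] < 3:
        raise ValueError("region must be an (n >= 3, 2) vertex array")
    poly = shapely.Polygon(region)
    if poly.area <= 1e-12:
        raise ValueError("degenerate polygon (zero area)")
    inside = shapely.intersects_xy(poly, fld.g.ravel(), fld.s.ravel()).reshape(fld.shape)
    return inside & fld.valid
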