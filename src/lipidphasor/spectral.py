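"""Spectral axes and emission spectra of the fluorescent components.

The analysis works on lambda stacks: each pixel carries an emission
spectrum sampled on a uniform wavelength grid.  Three emitters matter
here — Nile Red in polar lipid environments (red-shifted), Nile Red in
neutral lipid environments (blue-shifted), and membrane-anchored EGFP.
Their pure emission spectra define the reference vertices of the
three-component phasor decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralAxis",
    "ComponentSpectrum",
    "make_component_spectrum",
    "default_axis",
    "default_spectra",
    "COMPONENT_IDS",
]

#: Canonical order of the three components everywhere in the package.
COMPONENT_IDS = ("polar_nilered", "neutral_nilered", "egfp")


@dataclass(frozen=True)
class SpectralAxis:
    """Uniform emission-wavelength grid of a lambda stack.

    Parameters
    ----------
    start : float
        Left edge of the first detection channel, in nm.
    bandwidth : float
        Spectral width of each channel, in nm.
    n_channels : int
        Number of detection channels (>= 3).
    """

    start: float
    bandwidth: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.n_channels < 3:
            raise ValueError(f"need at least 3 channels, got {self.n_channels}")
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be positive, got {self.bandwidth}")

    @property
    def end(self) -> float:
        """Right edge of the last channel, in nm."""
        return self.start + self.n_channels * self.bandwidth

    @property
    def centers(self) -> np.ndarray:
        """Center wavelength of each channel, in nm."""
        k = np.arange(self.n_channels)
        return self.start + (k + 0.5) * self.bandwidth


def default_axis() -> SpectralAxis:
    """The acquisition grid used throughout: 22 channels of 10 nm from 493 nm."""
    return SpectralAxis(start=493.0, bandwidth=10.0, n_channels=22)


@dataclass(frozen=True)
class ComponentSpectrum:
    """Unit-intensity emission spectrum of one component on a spectral axis.

    ``values`` is nonnegative and sums to 1, so that mixing fractions act
    directly on emitted photon counts.
    """

    component_id: str
    peak: float
    fwhm: float
    axis: SpectralAxis
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.axis.n_channels,):
            raise ValueError("spectrum length does not match axis")
        if np.any(v < 0):
            raise ValueError("spectrum has negative samples")
        if not np.isclose(v.sum(), 1.0, atol=1e-9):
            raise ValueError("spectrum is not normalized to unit total intensity")
        object.__setattr__(self, "values", v)


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def make_component_spectrum(
    component_id: str, peak: float, fwhm: float, axis: SpectralAxis
) -> ComponentSpectrum:
    """Sample a Gaussian emission band on ``axis`` and normalize to unit sum.

    Parameters
    ----------
    component_id : str
        Free-form label; the canonical components use ``polar_nilered``,
        ``neutral_nilered`` and ``egfp``.
    peak : float
        Emission maximum in nm.  Must lie within ``[axis.start - fwhm,
        axis.end + fwhm]``; further out the component is invisible on the
        detector and the spectrum cannot be normalized meaningfully.
    fwhm : float
        Full width at half maximum in nm (> 0).
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    if not (axis.start - fwhm <= peak <= axis.end + fwhm):
        raise ValueError(
            f"peak {peak} nm is outside the visible range "
            f"[{axis.start - fwhm}, {axis.end + fwhm}] nm of the axis"
        )
    sigma = fwhm * _FWHM_TO_SIGMA
    v = np.exp(-0.5 * ((axis.centers - peak) / sigma) ** 2)
    total = v.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("spectrum vanishes on the axis")
    return ComponentSpectrum(component_id, peak, fwhm, axis, v / total)


def default_spectra(axis: SpectralAxis | None = None) -> dict[str, ComponentSpectrum]:
    """Default emission bands of the three components.

    EGFP peaks at 509 nm (FWHM 40 nm).  Nile Red in neutral-lipid
    environments (droplet cores) is blue-shifted, peak 580 nm / FWHM
    60 nm, relative to polar-lipid environments (membranes), peak
    635 nm / FWHM 75 nm.  Generic photophysics defaults; everything is
    configurable.
    """
    if axis is None:
        axis = default_axis()
    return {
        "polar_nilered": make_component_spectrum("polar_nilered", 635.0, 75.0, axis),
        "neutral_nilered": make_component_spectrum("neutral_nilered", 580.0, 60.0, axis),
        "egfp": make_component_spectrum("egfp", 509.0, 40.0, axis),
    }
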