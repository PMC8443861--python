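"""Vertex calibration and three-component barycentric unmixing.

A pixel containing a mixture of the three emitters sits, by the phasor
linear-combination property, inside the triangle spanned by the three
pure-component phasor positions (the reference vertices).  Solving the
barycentric coordinates of the pixel's (G, S) within that triangle
yields the per-pixel intensity fractions of polar Nile Red, neutral
Nile Red and EGFP.

Vertices are calibrated from control images: the two Nile Red vertices
from the phase-angle extremes of a wild-type larva stained with Nile Red
only (the dye's polarity trajectory), the EGFP vertex from an unstained
transgenic larva.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .phasor import PhasorField, phase_modulation

__all__ = [
    "ReferenceVertices",
    "FractionField",
    "NeutralFraction",
    "calibrate_nile_red_vertices",
    "calibrate_egfp_vertex",
    "unmix_three_component",
    "nile_red_neutral_fraction",
    "forward_mix",
]

_MIN_CALIBRATION_PIXELS = 100


def _triangle_area(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    return 0.5 * abs((q[0] - p[0]) * (r[1] - p[1]) - (r[0] - p[0]) * (q[1] - p[1]))


@dataclass(frozen=True)
class ReferenceVertices:
    """Calibrated phasor positions of the three pure components.

    Order everywhere: (polar Nile Red, neutral Nile Red, EGFP).
    """

    v_polar: tuple[float, float]
    v_neutral: tuple[float, float]
    v_egfp: tuple[float, float]

    def __post_init__(self) -> None:
        vs = [np.asarray(v, dtype=float) for v in (self.v_polar, self.v_neutral, self.v_egfp)]
        for name, v in zip(("v_polar", "v_neutral", "v_egfp"), vs):
            if v.shape != (2,):
                raise ValueError(f"{name} must be a (G, S) pair")
            if np.hypot(*v) > 1.0 + 1e-9:
                raise ValueError(f"{name} lies outside the unit circle")
        if _triangle_area(*vs) <= 1e-6:
            raise ValueError("vertices are (near-)collinear: triangle area <= 1e-6")

    def as_matrix(self) -> np.ndarray:
        """Columns are the vertices in component order, rows (G, S)."""
        return np.column_stack([self.v_polar, self.v_neutral, self.v_egfp]).astype(float)


@dataclass
class FractionField:
    """Per-pixel barycentric fractions (polar, neutral, EGFP).

    ``alpha[..., i]`` sums to 1 over i for every valid pixel; fractions
    are clipped to [0, 1].  ``in_triangle`` is False where the raw
    barycentric solution had a negative component (noise pushed the pixel
    outside the calibration triangle).
    """

    alpha: np.ndarray  # (..., 3) in order (polar, neutral, egfp)
    in_triangle: np.ndarray
    valid: np.ndarray

    @property
    def alpha_polar(self) -> np.ndarray:
        return self.alpha[..., 0]

    @property
    def alpha_neutral(self) -> np.ndarray:
        return self.alpha[..., 1]

    @property
    def alpha_egfp(self) -> np.ndarray:
        return self.alpha[..., 2]


def _weighted_centroid(fld: PhasorField, mask: np.ndarray) -> np.ndarray:
    w = fld.total_intensity[mask]
    return np.array([np.average(fld.g[mask], weights=w), np.average(fld.s[mask], weights=w)])


def calibrate_nile_red_vertices(
    control: PhasorField, low_q: float = 2.0, high_q: float = 98.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Estimate the two Nile Red vertices from a dye-only control field.

    Valid pixels are ordered by phase angle; the blue-shifted (neutral)
    vertex is the intensity-weighted mean phasor of pixels below the
    ``low_q``-th phase percentile, the red-shifted (polar) vertex the same
    above the ``high_q``-th.  Deterministic replacement for manual cursor
    placement at the trajectory extremes.

    Returns ``(v_polar, v_neutral)``.
    """
    if not (0.0 <= low_q < high_q <= 100.0):
        raise ValueError("need 0 <= low_q < high_q <= 100")
    if int(control.valid.sum()) < _MIN_CALIBRATION_PIXELS:
        raise ValueError(
            f"too few valid pixels for calibration: {int(control.valid.sum())} < "
            f"{_MIN_CALIBRATION_PIXELS}"
        )
    theta, _ = phase_modulation(control)
    th = theta[control.valid]
    lo, hi = np.percentile(th, [low_q, high_q])
    low_mask = control.valid & (np.nan_to_num(theta, nan=np.inf) <= lo)
    high_mask = control.valid & (np.nan_to_num(theta, nan=-np.inf) >= hi)
    v_neutral = _weighted_centroid(control, low_mask)
    v_polar = _weighted_centroid(control, high_mask)
    if np.hypot(*(v_polar - v_neutral)) < 1e-3:
        raise ValueError("Nile Red trajectory collapsed: extreme vertices coincide")
    return (float(v_polar[0]), float(v_polar[1])), (float(v_neutral[0]), float(v_neutral[1]))


def calibrate_egfp_vertex(control: PhasorField) -> tuple[float, float]:
    """Intensity-weighted phasor centroid of an EGFP-only control field."""
    if int(control.valid.sum()) < _MIN_CALIBRATION_PIXELS:
        raise ValueError(
            f"too few valid pixels for calibration: {int(control.valid.sum())} < "
            f"{_MIN_CALIBRATION_PIXELS}"
        )
    v = _weighted_centroid(control, control.valid)
    return (float(v[0]), float(v[1]))


def unmix_three_component(fld: PhasorField, vertices: ReferenceVertices) -> FractionField:
    """Barycentric decomposition of each pixel's phasor in the vertex triangle.

    Solves, per pixel, the linear system

        [G]   [G_p  G_n  G_e] [a_p]
        [S] = [S_p  S_n  S_e] [a_n]
        [1]   [ 1    1    1 ] [a_e]

    Raw solutions with a negative coordinate (pixels outside the
    triangle) are clipped to [0, 1], renormalized to sum 1, and flagged
    ``in_triangle = False`` so downstream stages can exclude them.
    """
    m = np.vstack([vertices.as_matrix(), np.ones(3)])
    try:
        m_inv = np.linalg.inv(m)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by vertex invariant
        raise ValueError("collinear vertices: unmixing system is singular") from exc
    rhs = np.stack([fld.g, fld.s, np.ones_like(fld.g)], axis=-1)
    raw = rhs @ m_inv.T
    in_triangle = np.all(raw >= -1e-9, axis=-1) & fld.valid
    alpha = np.clip(raw, 0.0, 1.0)
    total = alpha.sum(axis=-1, keepdims=True)
    alpha = np.where(total > 0, alpha / np.where(total > 0, total, 1.0), 1.0 / 3.0)
    alpha[~fld.valid] = 0.0
    return FractionField(alpha=alpha, in_triangle=in_triangle, valid=fld.valid.copy())


class NeutralFraction(NamedTuple):
    """Per-pixel neutral-lipid fraction f(x) in percent, with defined-ness."""

    f: np.ndarray  # percent, NaN where undefined
    defined: np.ndarray  # bool


def nile_red_neutral_fraction(fractions: FractionField, eps: float = 0.05) -> NeutralFraction:
    """Percent of a pixel's Nile Red signal in the neutral component.

    f(x) = 100 * a_neutral / (a_neutral + a_polar).  Pixels whose total
    Nile Red share falls below ``eps`` (essentially pure EGFP) carry no
    polarity information; they are flagged undefined (NaN) and excluded
    downstream, never raised.
    """
    denom = fractions.alpha_polar + fractions.alpha_neutral
    defined = fractions.valid & (denom >= eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 100.0 * fractions.alpha_neutral / denom
    f = np.where(defined, f, np.nan)
    return NeutralFraction(f=f, defined=defined)


def forward_mix(vertices: ReferenceVertices, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Phasor coordinates of pixels with known fractions (the forward model).

    ``alpha`` has shape (..., 3) in component order; returns (g, s).
    Inverse of :func:`unmix_three_component` for in-triangle fractions.
    """
    m = vertices.as_matrix()  # 2 x 3
    gs = np.asarray(alpha, dtype=float) @ m.T
    return gs[..., 0], gs[..., 1]
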