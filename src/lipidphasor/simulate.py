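"""Synthetic hyperspectral scenes with known ground truth.

No raw larval lambda stacks are publicly deposited, so validation runs
on generated scenes that emulate the study conditions: EGFP-labeled
cells whose Nile Red signal mixes a polar (membrane) and a neutral
(lipid droplet) environment, imaged on a 22-channel, 10 nm, 493–713 nm
detection grid with Poisson photon noise.

Cell geometries mirror the two morphologies seen in vivo: rounded cells
filled with a lipid droplet (neutral-rich core with a thin polar rim —
the polar pixels surround the whole cell) and irregular droplet-free
cells dominated by polar lipids.  Mixing is intensity-weighted: a
pixel's fractions are fractions of emitted photons, matching the phasor
linear-combination interpretation.

Ground truth (per-pixel fractions, cell labels, per-cell CM/DR computed
from the noise-free fractions) is recorded before noise is applied, so
it is invariant to the noise seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phasor import HyperspectralImage
from .spectral import (
    COMPONENT_IDS,
    ComponentSpectrum,
    SpectralAxis,
    default_axis,
    default_spectra,
)

__all__ = [
    "CellSpec",
    "SceneConfig",
    "SceneGroundTruth",
    "render_scene",
    "render_calibration_controls",
    "cohort_config",
]

CELL_SHAPES = ("round_droplet", "irregular_no_droplet", "multi_droplet")


@dataclass(frozen=True)
class CellSpec:
    """Geometry and composition of one synthetic cell.

    ``egfp`` is the EGFP photon fraction of every cell pixel;
    ``neutral_core`` / ``neutral_base`` set the neutral share of the
    Nile Red signal inside droplet regions and elsewhere in the cell.
    ``orientation`` rotates the lobes of irregular shapes (radians).
    """

    shape: str
    center: tuple[float, float]  # (row, col)
    radius: float
    egfp: float = 0.3
    neutral_core: float = 0.85
    neutral_base: float = 0.10
    rim_width: float = 1.2
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in CELL_SHAPES:
            raise ValueError(f"unknown cell shape {self.shape!r}; choose from {CELL_SHAPES}")
        if self.radius <= 1:
            raise ValueError("radius must exceed 1 pixel")
        for name in ("egfp", "neutral_core", "neutral_base"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic acquisition.

    ``photon_budget`` is the expected signal count per cell pixel (the
    component spectra integrate to 1); ``background`` is an additive
    expected count per pixel per channel (flat autofluorescence floor).
    ``seed`` drives the noise only — geometry and ground truth are
    seed-independent.
    """

    shape: tuple[int, int] = (256, 256)
    cells: tuple[CellSpec, ...] = ()
    background: float = 2.0
    photon_budget: float = 1000.0
    poisson: bool = True
    read_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_budget < 0 or self.background < 0:
            raise ValueError("photon_budget and background must be nonnegative")
        if self.photon_budget == 0 and self.background == 0:
            raise ValueError("empty scene: zero photon budget and zero background")


@dataclass
class SceneGroundTruth:
    """Pre-noise truth of a rendered scene.

    ``fractions`` has shape (rows, cols, 3) in (polar, neutral, egfp)
    order and sums to 1 on cell pixels (labels > 0); background pixels
    carry zero fractions.  ``cell_stats`` holds per-cell CM/DR/class
    computed from the true fractions.
    """

    fractions: np.ndarray
    labels: np.ndarray
    cell_stats: pd.DataFrame


def _neutral_share_map(spec: CellSpec, rr: np.ndarray, cc: np.ndarray):
    """Boolean cell mask and per-pixel neutral share nu for one cell."""
    dr = rr - spec.center[0]
    dc = cc - spec.center[1]
    dist = np.hypot(dr, dc)
    if spec.shape == "irregular_no_droplet":
        ang = np.arctan2(dc, dr)
        local_r = spec.radius * (1.0 + 0.3 * np.sin(3.0 * ang + spec.orientation))
        inside = dist <= local_r
        nu = np.full(inside.shape, spec.neutral_base)
        return inside, nu
    inside = dist <= spec.radius
    nu = np.full(inside.shape, spec.neutral_base)
    if spec.shape == "round_droplet":
        # neutral-rich droplet core, thin polar rim around the whole cell
        core = dist <= spec.radius - spec.rim_width
        nu[core] = spec.neutral_core
    else:  # multi_droplet
        offs = 0.45 * spec.radius
        for k in range(3):
            a = spec.orientation + 2.0 * np.pi * k / 3.0
            d = np.hypot(dr - offs * np.cos(a), dc - offs * np.sin(a))
            nu[d <= spec.radius / 3.0] = spec.neutral_core
    return inside, nu


def _ground_truth_stats(fractions: np.ndarray, labels: np.ndarray, cells) -> pd.DataFrame:
    from .profiles import cell_polarity_profile  # local import avoids a cycle
    from .unmix import FractionField, nile_red_neutral_fraction

    fr = FractionField(
        alpha=fractions, in_triangle=labels > 0, valid=labels > 0
    )
    f, _ = nile_red_neutral_fraction(fr)
    rows = []
    for cid, spec in enumerate(cells, start=1):
        mask = labels == cid
        if not mask.any():
            continue
        values = f[mask]
        values = values[np.isfinite(values)]
        if values.size == 0:
            cm = dr = np.nan
            label = "undefined"
        else:
            p = cell_polarity_profile(values)
            cm, dr, label = p.cm, p.dr, p.class_label
        rows.append(
            {
                "cell_id": cid,
                "shape": spec.shape,
                "size": int(mask.sum()),
                "cm": cm,
                "dr": dr,
                "class": label,
            }
        )
    return pd.DataFrame(rows)


def _spectra_matrix(spectra: dict[str, ComponentSpectrum]) -> np.ndarray:
    missing = [c for c in COMPONENT_IDS if c not in spectra]
    if missing:
        raise ValueError(f"missing component spectra: {missing}")
    peaks = {c: spectra[c].peak for c in COMPONENT_IDS}
    if peaks["neutral_nilered"] >= peaks["polar_nilered"]:
        raise ValueError("neutral Nile Red must be blue-shifted relative to polar")
    m = np.stack([spectra[c].values for c in COMPONENT_IDS])  # (3, C)
    if any(
        np.allclose(m[i], m[j]) for i in range(3) for j in range(i + 1, 3)
    ):
        raise ValueError("component spectra must be pairwise distinct")
    return m


def _apply_noise(expected: np.ndarray, config: SceneConfig, rng: np.random.Generator):
    data = rng.poisson(expected).astype(float) if config.poisson else expected.copy()
    if config.read_noise_sigma > 0:
        data = data + rng.normal(0.0, config.read_noise_sigma, size=data.shape)
    return np.clip(data, 0.0, None)


def render_scene(
    config: SceneConfig,
    spectra: dict[str, ComponentSpectrum] | None = None,
    axis: SpectralAxis | None = None,
) -> tuple[HyperspectralImage, SceneGroundTruth]:
    """Render a configured scene and its pre-noise ground truth.

    The expected spectrum of a cell pixel is
    ``photon_budget * sum_x alpha_x * spectrum_x + background`` per
    channel; noise (Poisson shot noise, optional Gaussian read noise) is
    then applied.  Identical config (including seed) gives bit-identical
    output.
    """
    if axis is None:
        axis = default_axis()
    if spectra is None:
        spectra = default_spectra(axis)
    m = _spectra_matrix(spectra)
    h, w = config.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    fractions = np.zeros((h, w, 3))
    labels = np.zeros((h, w), dtype=np.int32)
    for cid, spec in enumerate(config.cells, start=1):
        inside, nu = _neutral_share_map(spec, rr, cc)
        nile = 1.0 - spec.egfp
        fractions[inside, 0] = nile * (1.0 - nu[inside])
        fractions[inside, 1] = nile * nu[inside]
        fractions[inside, 2] = spec.egfp
        labels[inside] = cid
    expected = config.photon_budget * (fractions @ m) + config.background
    rng = np.random.default_rng(config.seed)
    data = _apply_noise(expected, config, rng)
    image = HyperspectralImage(data=data, axis=axis)
    truth = SceneGroundTruth(
        fractions=fractions,
        labels=labels,
        cell_stats=_ground_truth_stats(fractions, labels, config.cells),
    )
    return image, truth


def render_calibration_controls(
    axis: SpectralAxis | None = None,
    spectra: dict[str, ComponentSpectrum] | None = None,
    photon_budget: float = 1000.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 256),
    background: float = 0.5,
    plateau: float = 0.02,
    poisson: bool = True,
) -> tuple[HyperspectralImage, HyperspectralImage]:
    """Render the two vertex-calibration control images.

    The first emulates a wild-type larva stained with Nile Red only: a
    polarity gradient sweeping the full neutral->polar trajectory across
    columns, with pure-component plateaus (``plateau`` fraction of the
    width) at both ends and no EGFP anywhere.  The plateau default
    matches the 2%/98% phase-percentile rule of the vertex calibration:
    the extreme 2% of pixels are exactly pure, so the percentile
    selection averages pure pixels with noise of both signs instead of
    picking the outward noise tail of a wide pure population.  The
    second image emulates an unstained transgenic larva: a central
    EGFP-only region over a flat background floor.
    """
    if photon_budget <= 0:
        raise ValueError("photon budget must be positive")
    if axis is None:
        axis = default_axis()
    if spectra is None:
        spectra = default_spectra(axis)
    m = _spectra_matrix(spectra)
    h, w = shape
    rng = np.random.default_rng(seed)

    # wild-type Nile Red control: column-wise neutral share 1 -> 0
    x = np.linspace(0.0, 1.0, w)
    nu = np.clip((1.0 - x - plateau) / (1.0 - 2.0 * plateau), 0.0, 1.0)
    frac = np.zeros((h, w, 3))
    frac[..., 0] = 1.0 - nu[None, :]
    frac[..., 1] = nu[None, :]
    expected = photon_budget * (frac @ m)
    cfg = SceneConfig(shape=shape, photon_budget=photon_budget, poisson=poisson, seed=seed)
    wildtype = HyperspectralImage(_apply_noise(expected, cfg, rng), axis)

    # unstained EGFP control: central block of pure EGFP, background floor
    frac_e = np.zeros((h, w, 3))
    frac_e[h // 4 : 3 * h // 4, w // 4 : 3 * w // 4, 2] = 1.0
    expected_e = photon_budget * (frac_e @ m) + background
    egfp_only = HyperspectralImage(_apply_noise(expected_e, cfg, rng), axis)
    return wildtype, egfp_only


def cohort_config(
    n_polar: int = 20,
    n_droplet: int = 20,
    seed: int = 0,
    photon_budget: float = 1000.0,
    background: float = 2.0,
    radius: float = 8.0,
    spacing: float = 34.0,
) -> SceneConfig:
    """Scene with a mixed cohort of droplet-free (polar) and droplet cells.

    Cells sit on a jittered grid with >= 3-pixel gaps; geometry is drawn
    from ``seed`` deterministically and the same seed also drives the
    render noise.  Emulates a field of differentiating adipocytes:
    droplet-free cells dominated by polar lipids next to droplet-filled
    cells with a neutral-rich core.
    """
    n = n_polar + n_droplet
    if n == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    ncols = int(np.ceil(np.sqrt(n * 1.6)))
    nrows = int(np.ceil(n / ncols))
    margin = spacing / 2 + 4
    kinds = ["irregular_no_droplet"] * n_polar + ["round_droplet"] * n_droplet
    rng.shuffle(kinds)
    cells = []
    for i, kind in enumerate(kinds):
        r, c = divmod(i, ncols)
        jitter = rng.uniform(-2.0, 2.0, size=2)
        cells.append(
            CellSpec(
                shape=kind,
                center=(margin + r * spacing + jitter[0], margin + c * spacing + jitter[1]),
                radius=radius + rng.uniform(-1.0, 1.0),
                orientation=rng.uniform(0, 2 * np.pi),
            )
        )
    shape = (
        int(2 * margin + (nrows - 1) * spacing + 2),
        int(2 * margin + (ncols - 1) * spacing + 2),
    )
    return SceneConfig(
        shape=shape,
        cells=tuple(cells),
        background=background,
        photon_budget=photon_budget,
        seed=seed,
    )
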