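"""Per-cell lipid polarity profiles: histogram, CM, DR and classification.

Each segmented cell is summarized by the normalized histogram of its
pixels' neutral-lipid fractions f(x) (percent of the Nile Red signal in
the neutral, blue-shifted component).  Two scalars characterize the
histogram:

* CM, the center of mass  CM = sum_bins b * f / sum_bins b  with b the
  percentage of cell pixels in each bin — a central-tendency value;
  low CM means mostly polar lipids.
* DR, the distribution range: the f(x) interval containing the central
  96% of the pixels, i.e. the difference between the f values at 2% and
  98% of the accumulated distribution — a dispersion value.

Cells are classified "within" the low-polarity region (DR < 30 and
CM < 60, the dashed-line thresholds of the reference analysis) or
"outside" it (every other cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .segment import CellRecord

__all__ = [
    "PolarityProfile",
    "ClassThresholds",
    "fraction_histogram",
    "center_of_mass",
    "distribution_range",
    "classify_cell",
    "cell_polarity_profile",
    "cohort_summary",
]


@dataclass(frozen=True)
class ClassThresholds:
    """Dashed-line cuts separating the two cell groups (defaults 60 / 30)."""

    cm_cut: float = 60.0
    dr_cut: float = 30.0

    def __post_init__(self) -> None:
        for name, v in (("cm_cut", self.cm_cut), ("dr_cut", self.dr_cut)):
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name} must be in (0, 100), got {v}")


@dataclass
class PolarityProfile:
    """Normalized neutral-fraction histogram of one cell with its summaries.

    Bins are centered on 0, ``bin_width``, 2*``bin_width``, ... 100 so a
    pixel at an integer percentage falls in the bin labeled by that
    percentage; ``b`` sums to 100.  ``cm``, ``dr`` and ``class_label``
    are filled by :func:`cell_polarity_profile` (or the individual
    operations).
    """

    bin_centers: np.ndarray
    b: np.ndarray  # percent of cell pixels per bin, sums to 100
    bin_width: float
    n_pixels: int
    cell_id: int | None = None
    cm: float | None = None
    dr: float | None = None
    class_label: str | None = None
    meta: dict = field(default_factory=dict)


def _bin_grid(bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Centers 0, w, 2w, ..., ~100 and the surrounding half-open edges."""
    if not (0 < bin_width <= 100):
        raise ValueError(f"bin_width must be in (0, 100], got {bin_width}")
    centers = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    edges = np.concatenate([centers - bin_width / 2, [centers[-1] + bin_width / 2]])
    return centers, edges


def fraction_histogram(
    cell: CellRecord | np.ndarray | Sequence[float], bin_width: float = 1.0
) -> PolarityProfile:
    """Normalized histogram of a cell's defined f(x) values.

    Accepts a :class:`~lipidphasor.segment.CellRecord` or a raw array of
    f values in percent.  NaNs (undefined pixels) are dropped; a cell
    with no defined pixel (pure EGFP) has no polarity profile and raises.
    """
    if isinstance(cell, CellRecord):
        values = np.asarray(cell.f_values, dtype=float)
        cell_id = cell.cell_id
    else:
        values = np.asarray(cell, dtype=float)
        cell_id = None
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cell has no pixels with a defined neutral fraction")
    if np.any((values < 0) | (values > 100)):
        raise ValueError("f(x) values must lie in [0, 100] percent")
    centers, edges = _bin_grid(bin_width)
    counts, _ = np.histogram(values, bins=edges)
    b = 100.0 * counts / counts.sum()
    return PolarityProfile(
        bin_centers=centers, b=b, bin_width=bin_width, n_pixels=values.size, cell_id=cell_id
    )


def center_of_mass(profile: PolarityProfile) -> float:
    """CM = sum(b * f) / sum(b) over bin centers (the histogram mean)."""
    return float(np.sum(profile.b * profile.bin_centers) / np.sum(profile.b))


def distribution_range(profile: PolarityProfile) -> float:
    """Width of the f(x) interval holding the central 96% of the pixels.

    The accumulated distribution of ``b`` is evaluated at the right edge
    of each bin; a quantile q is the smallest right edge whose
    accumulated percentage reaches q (inverted-CDF convention, resolution
    one bin).  DR = F^-1(98) - F^-1(2).
    """
    cum = np.cumsum(profile.b)
    right_edges = profile.bin_centers + profile.bin_width / 2.0

    def quantile(q: float) -> float:
        idx = int(np.searchsorted(cum, q - 1e-9))
        return float(right_edges[min(idx, len(right_edges) - 1)])

    return quantile(98.0) - quantile(2.0)


def classify_cell(
    cm: float, dr: float, thresholds: ClassThresholds | None = None
) -> str:
    """'within' the low-CM/low-DR region iff DR < dr_cut and CM < cm_cut.

    Every other cell — including boundary values and mixed quadrants —
    is 'outside'; the two groups partition all cells.
    """
    if thresholds is None:
        thresholds = ClassThresholds()
    if not (0.0 <= cm <= 100.0 and 0.0 <= dr <= 100.0):
        raise ValueError("CM and DR must lie in [0, 100]")
    if dr < thresholds.dr_cut and cm < thresholds.cm_cut:
        return "within"
    return "outside"


def cell_polarity_profile(
    cell: CellRecord | np.ndarray | Sequence[float],
    bin_width: float = 1.0,
    thresholds: ClassThresholds | None = None,
) -> PolarityProfile:
    """Histogram + CM + DR + class label for one cell, in one call."""
    profile = fraction_histogram(cell, bin_width=bin_width)
    profile.cm = center_of_mass(profile)
    profile.dr = distribution_range(profile)
    profile.class_label = classify_cell(profile.cm, profile.dr, thresholds)
    return profile


def cohort_summary(
    profiles_by_stage: Mapping[object, Iterable[PolarityProfile]],
    thresholds: ClassThresholds | None = None,
) -> pd.DataFrame:
    """Per-stage table of cell counts, class percentages and CM/DR lists.

    ``profiles_by_stage`` maps a stage label (e.g. days post
    fertilization) to that stage's cell profiles.  Profiles missing cm/dr
    are completed in place with the default bin grid already stored.
    """
    if thresholds is None:
        thresholds = ClassThresholds()
    rows = []
    for stage, profiles in profiles_by_stage.items():
        profiles = list(profiles)
        if not profiles:
            raise ValueError(f"stage {stage!r} has no cell profiles")
        cms, drs, labels = [], [], []
        for p in profiles:
            if p.cm is None:
                p.cm = center_of_mass(p)
            if p.dr is None:
                p.dr = distribution_range(p)
            p.class_label = classify_cell(p.cm, p.dr, thresholds)
            cms.append(p.cm)
            drs.append(p.dr)
            labels.append(p.class_label)
        n = len(profiles)
        n_within = sum(1 for lab in labels if lab == "within")
        rows.append(
            {
                "stage": stage,
                "n_cells": n,
                "pct_within": 100.0 * n_within / n,
                "pct_outside": 100.0 * (n - n_within) / n,
                "cm": cms,
                "dr": drs,
            }
        )
    if not rows:
        raise ValueError("empty cohort")
    return pd.DataFrame(rows)
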