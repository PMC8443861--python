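"""Segmentation of individual EGFP-positive cells.

The transgene labels adipocyte plasma membranes with EGFP, so
thresholding the unmixed EGFP fraction isolates the labeled cells and
excludes Nile Red signal coming from unlabeled neighbors.  Connected
components (4-connected by default, to limit bridging between adjacent
cells) become individual cell records.  Alternatively, the manual
phasor-plot workflow is reproduced by selecting a polygon in (G, S)
space and tracing it back to the image (reciprocity principle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .phasor import PhasorField, reciprocity_select

__all__ = ["CellRecord", "egfp_mask", "label_cells", "select_cell_by_phasor"]


@dataclass
class CellRecord:
    """One segmented cell: pixel set, neutral-fraction values, EGFP level.

    ``pixels`` is an (n, 2) array of 0-based (row, col) coordinates;
    ``f_values`` holds the defined f(x) values (percent) of the cell's
    pixels — undefined-f pixels count toward ``size`` but contribute no
    value.
    """

    cell_id: int
    pixels: np.ndarray
    f_values: np.ndarray
    size: int
    mean_egfp: float

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))


def egfp_mask(fractions, threshold: float = 0.2) -> np.ndarray:
    """Binary mask of EGFP-positive pixels: alpha_egfp >= threshold and valid."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (fractions.alpha_egfp >= threshold) & fractions.valid


def label_cells(
    mask: np.ndarray,
    f: np.ndarray | None = None,
    egfp: np.ndarray | None = None,
    min_size: int = 20,
    connectivity: int = 1,
) -> list[CellRecord]:
    """Connected-component labeling of a cell mask into cell records.

    Parameters
    ----------
    mask : bool array
        EGFP-positive (or phasor-selected) pixels.
    f : array, optional
        Per-pixel neutral fraction in percent, NaN where undefined.
    egfp : array, optional
        Per-pixel EGFP fraction, for the per-cell mean.
    min_size : int
        Components smaller than this are discarded (>= 1).
    connectivity : int
        1 = 4-connected (default), 2 = 8-connected.

    Components are labeled deterministically in raster order of their
    first pixel.  An empty mask yields an empty list.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    labels = measure.label(np.asarray(mask, bool), connectivity=connectivity)
    records: list[CellRecord] = []
    cell_id = 0
    # skimage labels components in raster order of first occurrence already
    for lab in range(1, labels.max() + 1):
        pix = np.argwhere(labels == lab)
        if pix.shape[0] < min_size:
            continue
        cell_id += 1
        idx = (pix[:, 0], pix[:, 1])
        if f is not None:
            fv = np.asarray(f, float)[idx]
            fv = fv[np.isfinite(fv)]
        else:
            fv = np.empty(0)
        mean_egfp = float(np.asarray(egfp, float)[idx].mean()) if egfp is not None else np.nan
        records.append(
            CellRecord(
                cell_id=cell_id,
                pixels=pix,
                f_values=fv,
                size=int(pix.shape[0]),
                mean_egfp=mean_egfp,
            )
        )
    return records


def select_cell_by_phasor(
    fld: PhasorField,
    region: np.ndarray,
    f: np.ndarray | None = None,
    egfp: np.ndarray | None = None,
    min_size: int = 20,
    connectivity: int = 1,
) -> list[CellRecord]:
    """Scriptable version of the manual phasor-ROI cell selection.

    Composition of :func:`~lipidphasor.phasor.reciprocity_select` (polygon
    in (G, S) space -> pixel mask) and :func:`label_cells`.
    """
    mask = reciprocity_select(fld, region)
    return label_cells(mask, f=f, egfp=egfp, min_size=min_size, connectivity=connectivity)
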