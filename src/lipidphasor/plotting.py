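"""Figure helpers: phasor plots, polarity profiles, CM-vs-DR scatters."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .phasor import PhasorField, phasor_histogram
from .profiles import ClassThresholds, PolarityProfile
from .unmix import ReferenceVertices

__all__ = ["plot_phasor", "plot_profiles", "plot_cm_dr", "plot_stage_fractions"]


def plot_phasor(
    fld: PhasorField,
    vertices: ReferenceVertices | None = None,
    bins: int = 201,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Phasor-plot density over the unit square with the unit circle overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    hist, ge, se = phasor_histogram(fld, bins=bins)
    masked = np.ma.masked_equal(hist.T, 0)
    ax.pcolormesh(ge, se, masked, cmap="viridis", rasterized=True)
    t = np.linspace(0, 2 * np.pi, 256)
    ax.plot(np.cos(t), np.sin(t), color="0.4", lw=0.8)
    if vertices is not None:
        for name, v in (
            ("polar NR", vertices.v_polar),
            ("neutral NR", vertices.v_neutral),
            ("EGFP", vertices.v_egfp),
        ):
            ax.plot(*v, "r^", ms=6)
            ax.annotate(name, v, textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set(xlim=(-1.05, 1.05), ylim=(-1.05, 1.05), xlabel="G", ylabel="S", aspect="equal")
    return ax


def plot_profiles(profiles: Iterable[PolarityProfile], ax: plt.Axes | None = None) -> plt.Axes:
    """Overlaid per-cell normalized neutral-fraction histograms."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        label = f"cell {p.cell_id}" if p.cell_id is not None else None
        ax.plot(p.bin_centers, p.b, lw=1.2, label=label)
    ax.set(xlabel="neutral lipid fraction f(x) [%]", ylabel="pixels [%]", xlim=(0, 100))
    handles, _ = ax.get_legend_handles_labels()
    if 0 < len(handles) <= 12:
        ax.legend(fontsize=7)
    return ax


def plot_cm_dr(
    per_cell: pd.DataFrame,
    thresholds: ClassThresholds | None = None,
    size_by_dr: bool = False,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """CM-vs-DR scatter with dashed classification cuts.

    ``per_cell`` needs columns ``cm`` and ``dr``; an optional ``stage``
    column colors the points.  With ``size_by_dr`` the dot area encodes
    DR (the bubble-plot variant).
    """
    if thresholds is None:
        thresholds = ClassThresholds()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sizes = 4 + per_cell["dr"] if size_by_dr else 18
    if "stage" in per_cell:
        for stage, sub in per_cell.groupby("stage"):
            s = 4 + sub["dr"] if size_by_dr else 18
            ax.scatter(sub["dr"], sub["cm"], s=s, alpha=0.7, label=str(stage))
        ax.legend(title="stage", fontsize=7)
    else:
        ax.scatter(per_cell["dr"], per_cell["cm"], s=sizes, alpha=0.7)
    ax.axvline(thresholds.dr_cut, ls="--", color="k", lw=0.8)
    ax.axhline(thresholds.cm_cut, ls="--", color="k", lw=0.8)
    ax.set(xlim=(0, 100), ylim=(0, 100), xlabel="distribution range DR [%]",
           ylabel="center of mass CM [%]")
    return ax


def plot_stage_fractions(summary: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Stacked per-stage percentages of the two cell classes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(len(summary))
    ax.bar(x, summary["pct_within"], label="DR<cut & CM<cut")
    ax.bar(x, summary["pct_outside"], bottom=summary["pct_within"], label="outside")
    ax.set_xticks(x, [str(s) for s in summary["stage"]])
    ax.set(xlabel="stage", ylabel="cells [%]", ylim=(0, 100))
    ax.legend(fontsize=7)
    return ax
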