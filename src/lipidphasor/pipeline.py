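"""End-to-end analysis workflow: calibrate, transform, unmix, segment,
profile, classify, compare.

A :class:`RunConfig` captures every tunable of a run; ``run_pipeline``
executes the stages in order and writes a per-cell table, the label
image, calibration, figures and a run log that records every parameter,
so a run can be re-executed identically from its log alone.
"""

from __future__ import annotations

import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import io as lpio
from .groupstats import TestResult, compare_cv, compare_median
from .phasor import HyperspectralImage, PhasorParams, compute_phasor
from .plotting import plot_cm_dr, plot_phasor, plot_profiles, plot_stage_fractions
from .profiles import ClassThresholds, PolarityProfile, cell_polarity_profile, cohort_summary
from .segment import egfp_mask, label_cells
from .simulate import cohort_config, render_calibration_controls, render_scene
from .spectral import SpectralAxis, default_axis
from .unmix import (
    ReferenceVertices,
    calibrate_egfp_vertex,
    calibrate_nile_red_vertices,
    nile_red_neutral_fraction,
    unmix_three_component,
)

__all__ = [
    "RunConfig",
    "ResultBundle",
    "calibrate_from_controls",
    "analyze_image",
    "run_pipeline",
    "export_report",
]


@dataclass
class RunConfig:
    """All tunables of one pipeline run.

    Inputs are either real lambda stacks (``image`` plus control images
    or a saved ``calibration``) or a synthetic cohort (``simulate``
    mapping passed to :func:`~lipidphasor.simulate.cohort_config`).
    """

    out_dir: str = "lipidphasor_run"
    image: str | None = None
    wildtype_control: str | None = None
    egfp_control: str | None = None
    calibration: str | None = None
    simulate: dict | None = None
    axis_start: float = 493.0
    axis_bandwidth: float = 10.0
    n_channels: int = 22
    harmonic: int = 1
    low_q: float = 2.0
    high_q: float = 98.0
    min_intensity: float | str = "otsu"
    background_subtract: bool = True
    calibration_min_intensity: float | None = None
    egfp_threshold: float = 0.2
    min_size: int = 20
    connectivity: int = 1
    nile_red_floor: float = 0.05
    bin_width: float = 1.0
    cm_cut: float = 60.0
    dr_cut: float = 30.0
    stage: str = "synthetic"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def axis(self) -> SpectralAxis:
        return SpectralAxis(self.axis_start, self.axis_bandwidth, self.n_channels)

    @property
    def thresholds(self) -> ClassThresholds:
        return ClassThresholds(cm_cut=self.cm_cut, dr_cut=self.dr_cut)


@dataclass
class ResultBundle:
    """Everything a completed run produced, in memory."""

    config: RunConfig
    vertices: ReferenceVertices
    per_cell: pd.DataFrame
    profiles: list[PolarityProfile]
    labels: np.ndarray
    stats: dict[str, TestResult]
    run_log: dict = field(default_factory=dict)


def calibrate_from_controls(
    wildtype: HyperspectralImage,
    egfp_only: HyperspectralImage,
    config: RunConfig | None = None,
) -> ReferenceVertices:
    """Reference vertices from the two control images.

    The calibration intensity threshold (default: 10% of the mean total
    intensity of each control) keeps dim background pixels from dragging
    the intensity-weighted vertex estimates toward the origin.
    """
    if config is None:
        config = RunConfig()
    params = PhasorParams(config.harmonic)

    def threshold(img: HyperspectralImage) -> float:
        if config.calibration_min_intensity is not None:
            return config.calibration_min_intensity
        return 0.1 * float(img.total_intensity.mean())

    wt_field = compute_phasor(wildtype, params, min_intensity=threshold(wildtype))
    eg_field = compute_phasor(egfp_only, params, min_intensity=threshold(egfp_only))
    v_polar, v_neutral = calibrate_nile_red_vertices(wt_field, config.low_q, config.high_q)
    v_egfp = calibrate_egfp_vertex(eg_field)
    return ReferenceVertices(v_polar=v_polar, v_neutral=v_neutral, v_egfp=v_egfp)


def _resolve_min_intensity(image: HyperspectralImage, setting: float | str) -> float:
    """Foreground threshold on total intensity; 'otsu' picks it automatically."""
    if setting == "otsu":
        from skimage.filters import threshold_otsu

        total = image.total_intensity
        if np.ptp(total) == 0:
            return 0.0
        return float(threshold_otsu(total))
    return float(setting)


def analyze_image(image: HyperspectralImage, vertices: ReferenceVertices, config: RunConfig):
    """Phasor -> unmix -> segment -> profile for one lambda stack.

    Background handling: the per-channel mean spectrum of sub-threshold
    pixels is subtracted before the transform (when enough background
    pixels exist), removing the systematic pull of an additive flat
    background toward the phasor origin.

    Returns ``(phasor_field, fractions, per_cell, profiles, labels)``.
    """
    min_intensity = _resolve_min_intensity(image, config.min_intensity)
    if config.background_subtract and min_intensity > 0:
        from .phasor import estimate_background_spectrum, subtract_background

        bg = estimate_background_spectrum(image, min_intensity)
        if bg is not None:
            image = subtract_background(image, bg)
            min_intensity = max(min_intensity - float(bg.sum()), 0.0)
    fld = compute_phasor(image, PhasorParams(config.harmonic), min_intensity=min_intensity)
    fractions = unmix_three_component(fld, vertices)
    f, _ = nile_red_neutral_fraction(fractions, eps=config.nile_red_floor)
    mask = egfp_mask(fractions, threshold=config.egfp_threshold)
    cells = label_cells(
        mask, f=f, egfp=fractions.alpha_egfp,
        min_size=config.min_size, connectivity=config.connectivity,
    )
    labels = np.zeros(fld.shape, dtype=np.int32)
    profiles = []
    rows = []
    for cell in cells:
        labels[cell.pixels[:, 0], cell.pixels[:, 1]] = cell.cell_id
        if cell.f_values.size == 0:
            continue  # pure-EGFP cell: no polarity profile
        p = cell_polarity_profile(cell, bin_width=config.bin_width, thresholds=config.thresholds)
        in_tri = float(fractions.in_triangle[cell.pixels[:, 0], cell.pixels[:, 1]].mean())
        p.meta.update(stage=config.stage, in_triangle_share=in_tri)
        profiles.append(p)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "stage": config.stage,
                "n_pixels": cell.size,
                "centroid_row": cell.centroid[0],
                "centroid_col": cell.centroid[1],
                "mean_egfp": cell.mean_egfp,
                "cm": p.cm,
                "dr": p.dr,
                "class": p.class_label,
                "in_triangle_share": in_tri,
            }
        )
    per_cell = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "stage", "n_pixels", "centroid_row", "centroid_col",
            "mean_egfp", "cm", "dr", "class", "in_triangle_share",
        ],
    )
    return fld, fractions, per_cell, profiles, labels


def _group_stats(per_cell: pd.DataFrame) -> dict[str, TestResult]:
    """CM and DR comparisons between the within/outside cell groups."""
    stats: dict[str, TestResult] = {}
    a = per_cell.loc[per_cell["class"] == "within"]
    b = per_cell.loc[per_cell["class"] == "outside"]
    if len(a) >= 3 and len(b) >= 3:
        for var in ("cm", "dr"):
            stats[f"{var}_median"] = compare_median(a[var], b[var])
            try:
                stats[f"{var}_cv"] = compare_cv(a[var], b[var])
            except ValueError:
                pass
    return stats


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full workflow described by ``config``.

    Stages: load/simulate inputs -> calibrate vertices -> phasor
    transform -> three-component unmixing -> EGFP-cell segmentation ->
    per-cell polarity profiles -> classification -> group statistics ->
    outputs.  A failing stage aborts with a stage-named error and
    removes any partial outputs.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        truth = None
        stage = "inputs"
        axis = config.axis
        if config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            scene = cohort_config(**sim)
            image, truth = render_scene(scene)
            axis = image.axis
        elif config.image:
            image = lpio.read_hyperspectral(config.image, axis=axis)
            axis = image.axis
        else:
            raise ValueError("config provides neither an input image nor a simulate block")

        stage = "calibration"
        if config.calibration:
            vertices, _ = lpio.load_vertices(config.calibration)
        elif config.wildtype_control and config.egfp_control:
            wt = lpio.read_hyperspectral(config.wildtype_control, axis=axis)
            eg = lpio.read_hyperspectral(config.egfp_control, axis=axis)
            vertices = calibrate_from_controls(wt, eg, config)
        elif config.simulate is not None:
            budget = config.simulate.get("photon_budget", 1000.0)
            wt, eg = render_calibration_controls(
                axis=axis, photon_budget=budget, seed=config.seed + 1
            )
            vertices = calibrate_from_controls(wt, eg, config)
        else:
            raise ValueError("no calibration file and no control images provided")

        stage = "analysis"
        fld, fractions, per_cell, profiles, labels = analyze_image(image, vertices, config)

        stage = "statistics"
        stats = _group_stats(per_cell)

        stage = "outputs"
        per_cell.to_csv(out / "per_cell.csv", index=False)
        lpio.write_label_image(out / "labels.tif", labels)
        lpio.save_vertices(
            out / "calibration.yaml", vertices,
            provenance={"harmonic": config.harmonic, "low_q": config.low_q,
                        "high_q": config.high_q, "seed": config.seed},
        )
        if truth is not None:
            lpio.write_ground_truth(out / "ground_truth", truth)
        stats_rows = [
            {"comparison": k, "test": r.test, "statistic": r.statistic,
             "pvalue": r.pvalue, "n_within": r.n[0], "n_outside": r.n[1], "note": r.note}
            for k, r in stats.items()
        ]
        pd.DataFrame(
            stats_rows,
            columns=["comparison", "test", "statistic", "pvalue",
                     "n_within", "n_outside", "note"],
        ).to_csv(out / "group_stats.csv", index=False)
        run_log = {
            "config": asdict(config),
            "vertices": {
                "v_polar": list(vertices.v_polar),
                "v_neutral": list(vertices.v_neutral),
                "v_egfp": list(vertices.v_egfp),
            },
            "n_cells": int(len(per_cell)),
        }
        (out / "run_log.yaml").write_text(yaml.safe_dump(run_log, sort_keys=False))

        bundle = ResultBundle(
            config=config, vertices=vertices, per_cell=per_cell,
            profiles=profiles, labels=labels, stats=stats, run_log=run_log,
        )
        export_report(bundle, out, fld=fld)
        return bundle
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def export_report(bundle: ResultBundle, out_dir: str | Path, fld=None) -> list[Path]:
    """Write the report figures: profiles, CM-vs-DR scatter, stage bars, phasor."""
    if not bundle.profiles:
        raise ValueError("empty bundle: no cell profiles to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    ax = plot_profiles(bundle.profiles)
    ax.figure.savefig(out / "profiles.png", dpi=150)
    plt.close(ax.figure)
    written.append(out / "profiles.png")

    ax = plot_cm_dr(bundle.per_cell, bundle.config.thresholds)
    ax.figure.savefig(out / "cm_dr_scatter.png", dpi=150)
    plt.close(ax.figure)
    written.append(out / "cm_dr_scatter.png")

    by_stage = {s: list(p) for s, p in _profiles_by_stage(bundle).items()}
    summary = cohort_summary(by_stage, bundle.config.thresholds)
    ax = plot_stage_fractions(summary)
    ax.figure.savefig(out / "stage_fractions.png", dpi=150)
    plt.close(ax.figure)
    written.append(out / "stage_fractions.png")

    if fld is not None:
        ax = plot_phasor(fld, bundle.vertices)
        ax.figure.savefig(out / "phasor.png", dpi=150)
        plt.close(ax.figure)
        written.append(out / "phasor.png")
    return written


def _profiles_by_stage(bundle: ResultBundle):
    by_stage: dict[str, list[PolarityProfile]] = {}
    for p in bundle.profiles:
        by_stage.setdefault(p.meta.get("stage", "all"), []).append(p)
    return by_stage
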