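# lipidphasor

Spectral-phasor analysis of hyperspectral Nile Red fluorescence for
in vivo lipid-metabolic profiling of single cells, in the presence of an
EGFP membrane label.

## The problem

Nile Red is solvatochromic: its emission is blue-shifted in neutral-lipid
environments (lipid droplet cores) and red-shifted in polar-lipid
environments (membranes). Imaging a labeled animal with a spectral
detector yields a lambda stack — an emission spectrum per pixel — from
which the local lipid polarity can be read out without fitting any model.
When the cells of interest additionally express membrane-anchored EGFP
(e.g. differentiating adipocytes in zebrafish larvae carrying an
adipocyte-specific EGFP-CAAX transgene), the green emission mixes into
every pixel and must be separated from the dye signal before the polarity
can be quantified.

`lipidphasor` implements that analysis as a scriptable pipeline:

1. **Spectral phasor transform.** Each pixel's spectrum I(λ) over N
   channels is reduced to the first Fourier harmonic, normalized by total
   intensity:

       G = Σₖ Iₖ cos(2πnk/N) / Σₖ Iₖ,   S = Σₖ Iₖ sin(2πnk/N) / Σₖ Iₖ

   The phase angle Θ = atan2(S, G) encodes the spectral peak (red shifts
   increase Θ) and the modulation M = √(G²+S²) the band width (narrower
   bands increase M). The transform is linear: a mixture of emitters
   lands at the intensity-weighted combination of the pure phasors.
2. **Three-component unmixing.** The phasor positions of polar Nile Red,
   neutral Nile Red and EGFP form a triangle; solving each pixel's
   barycentric coordinates in it gives the per-pixel photon fractions
   (α_polar, α_neutral, α_EGFP). The Nile Red vertices are calibrated
   from a dye-only (wild-type) control via the phase-angle extremes of
   the polarity trajectory; the EGFP vertex from an unstained transgenic
   control.
3. **Cell profiles.** EGFP-positive cells are segmented (threshold on
   α_EGFP, 4-connected components, or a phasor-plot polygon traced back
   to the image via the reciprocity principle). Each cell's pixels give a
   neutral-lipid fraction f(x) = 100·α_neutral/(α_neutral+α_polar); the
   normalized histogram of f(x) is summarized by its **center of mass
   (CM)** and its **distribution range (DR)** — the width of the interval
   holding the central 96% of the pixels (2%–98% of the accumulated
   distribution). Cells with DR < 30 and CM < 60 form the
   polar-dominated ("within") group; all others are "outside".
4. **Group statistics.** Medians are compared with Mann–Whitney U,
   relative spread with Fligner–Killeen, and a Shapiro–Wilk/Levene-gated
   procedure routes multi-group comparisons to Kruskal–Wallis +
   Bonferroni or rank-transform + Welch ANOVA + Games–Howell.

Because no raw larval lambda stacks are publicly available, the package
ships a synthetic-scene generator (`lipidphasor.simulate`) producing
droplet-filled and droplet-free cells with known per-pixel fractions,
Poisson photon noise and full ground truth, which the test suite uses to
validate the pipeline end to end.

## Worked example

```python
from lipidphasor.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="demo",
    simulate={"n_polar": 6, "n_droplet": 6, "photon_budget": 1000},
    seed=42,
)
bundle = run_pipeline(cfg)
print(bundle.per_cell[["cell_id", "n_pixels", "cm", "dr", "class"]].round(1))
```

which prints

```
 cell_id  n_pixels   cm   dr   class
       1       159 62.1 82.0 outside
       2       206 11.0 12.0  within
       ...
      12       174 11.4 13.0  within
```

The six droplet-free cells land at CM ≈ 11, DR ≈ 12 (their Nile Red sits
almost entirely in the polar component, so the histogram is a single
narrow peak near f = 10%); the six droplet cells land at CM ≈ 64,
DR ≈ 82 (neutral-rich core at f ≈ 85% plus a polar rim, a wide bimodal
histogram). The group comparisons in `bundle.stats` separate the two
classes (e.g. Mann–Whitney on CM: U = 0, p = 0.002). The output directory
contains the per-cell CSV, the 16-bit label image, the calibration YAML,
phasor/profile/scatter figures and a run log sufficient to replay the run.

The same workflow is available from the shell:

```bash
lipidphasor simulate --config scene.yaml --seed 1 --out sim/
lipidphasor run --config run.yaml --seed 1 --out results/
lipidphasor stats --percell results/per_cell.csv --value cm
```

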