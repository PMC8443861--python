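# Methods

## Phasor transform

The spectral phasor of a pixel with channel intensities I₀…I_{N−1} is

    G = Σₖ Iₖ cos(2πnk/N) / Σₖ Iₖ,   S = Σₖ Iₖ sin(2πnk/N) / Σₖ Iₖ,

with n the harmonic (default 1) and k the **channel index**. Anchoring
the Fourier argument at the channel index rather than at a wavelength
offset is self-consistent and reversible on a uniform grid (a circular
shift of the spectrum by m channels rotates the phasor by 2πnm/N);
wavelengths are carried as metadata only. For nonnegative spectra the
phasor lies inside the unit circle; the phase angle grows with red
spectral shift and the modulation with band narrowing. Pixels with zero
(or sub-threshold) total intensity are flagged invalid and excluded from
every downstream statistic instead of being placed at the origin, where
they would contaminate the phasor cloud. No spatial smoothing of G/S is
applied anywhere.

## Background handling

An additive flat background of b counts/channel drags every phasor
radially toward the origin by a factor T/(T+Nb) (T = signal counts).
This is a genuine bias, not noise: at 500 signal counts and b = 2 over
22 channels it shifts droplet-cell CM estimates by ≈3 percentage
points. The pipeline therefore estimates the background spectrum as the
per-channel mean of sub-threshold pixels and subtracts it (clipped at
zero) before the transform, whenever at least 50 background pixels
exist. The foreground threshold itself defaults to Otsu's method on
total intensity — deterministic, parameter-free, and appropriate for
images with a clear foreground/background intensity split; a fixed
threshold can be configured instead, and the raw transform keeps its
threshold-off default.

## Vertex calibration

The two Nile Red vertices are the intensity-weighted mean phasors of the
valid pixels below the 2nd and above the 98th percentile of phase angle
in a dye-only control — a deterministic, logged replacement for manual
cursor placement at the trajectory extremes. The EGFP vertex is the
intensity-weighted phasor centroid of an unstained-transgenic control.
Manual vertices can be supplied via the calibration YAML.

Percentile selection on a noisy cloud has a subtlety: if a large
fraction of control pixels is exactly pure, the extreme-percentile
subset is the outward noise tail of that pure population and the vertex
estimate overshoots by ≈1.6σ of the per-pixel phasor noise. The
synthetic wild-type control therefore holds its pure-component plateaus
to the same 2% of columns as the percentile rule, so the selected pixels
are the pure population with noise of both signs; measured vertex errors
at a 1000-count photon budget are then ≤0.017 in (G, S), against ≈0.03
for a 15%-plateau design.

## Unmixing

Per pixel the system [G; S; 1] = V·α with V the 3×3 vertex matrix
(rows G, S, 1) is solved by a single precomputed inverse; α are the
barycentric coordinates. Solutions with a negative component (noise
pushes pixels slightly outside the triangle) are clipped to [0, 1],
renormalized to sum 1, and flagged `in_triangle = False` so downstream
stages can exclude them; discarding them outright would bias against
pixels near edges. Noiseless forward-mixed pixels are recovered to
machine precision; under pure Poisson noise the mean absolute fraction
error over uniformly drawn in-triangle fractions is ≈0.015 at a
1000-count budget and ≈0.021 at 500 counts (error scales as the inverse
square root of the photon budget).

The neutral-lipid fraction f = 100·α_neutral/(α_neutral+α_polar) is
undefined where the total Nile Red share falls below ε = 0.05
(essentially pure EGFP); such pixels are flagged, not raised, and count
toward cell size but contribute no histogram mass.

## Cell segmentation

EGFP-positive pixels (α_EGFP ≥ 0.2 by default) are grouped by
4-connected component labeling (4- rather than 8-connectivity to limit
bridging between adjacent cells); components under 20 pixels are
dropped. Labels follow raster order of each component's first pixel, so
segmentation is deterministic. Touching cells merge — no watershed
splitting is attempted, matching the granularity of manual per-cell
selection that this module replaces. The phasor-polygon route
(`select_cell_by_phasor`) composes reciprocity selection with the same
labeling.

## CM, DR and classification

Cell histograms use bins **centered** on 0, 1, …, 100% (half-integer
edges) at the default 1% width, so integer-valued fractions land in the
bin labeled by their value; b is normalized to sum 100. CM is the
histogram mean Σb·f/Σb, which matches the unbinned pixel mean to within
half a bin. DR is the width of the central-96% interval of the
accumulated distribution: a quantile q is the smallest bin right edge
whose cumulative mass reaches q (inverted-CDF convention), and
DR = F⁻¹(98) − F⁻¹(2). This step-inverse makes a point mass give DR = 0,
two equal masses at 10/90 give DR = 80, and an exactly uniform spread
over 0–100% give DR = 96; a within-bin interpolation rule would offset
each of these by up to one bin width. DR resolution is therefore one bin.

Classification: a cell is "within" the polar-dominated region iff
DR < 30 **and** CM < 60 (strict inequalities); every other cell —
boundary values and mixed quadrants included — is "outside", so the two
groups partition any cohort. Both cuts are configurable.

## Group statistics

`compare_median` is the two-sided Mann–Whitney U (exact null for both
n < 8 without ties, tie-corrected normal approximation otherwise; fully
tied data return p = 1 with a warning). `compare_cv` is Fligner–Killeen,
χ²-approximated, on raw values. `gated_compare` applies Shapiro–Wilk
(per group) and Brown–Forsythe/Levene gates at α = 0.05 (configurable):
non-normal + homoscedastic → Kruskal–Wallis (Mann–Whitney for two
groups) with Bonferroni-corrected pairwise tests; non-normal +
heteroscedastic → rank transform of the pooled data, Welch ANOVA,
Games–Howell post hoc. The normal branches are not prescribed by the
gating scheme this reproduces; they are completed with one-way ANOVA
(homoscedastic) and Welch ANOVA + Games–Howell (heteroscedastic). The
executed branch is always reported alongside the gate p-values.

## Synthetic scenes

The generator emulates the study conditions: a 22-channel, 10 nm,
493–713 nm detection grid; Gaussian emission bands (EGFP 509/40 nm,
neutral Nile Red 580/60 nm, polar Nile Red 635/75 nm FWHM — generic
photophysics defaults, the real bands are asymmetric but their phasor
geometry is comparable); intensity-weighted mixing (fractions are
fractions of emitted photons); Poisson shot noise on expected counts
plus optional Gaussian read noise; a flat background floor (2
counts/channel) standing in for autofluorescence. The default photon
budget is 1000 expected signal counts per cell pixel — no detector
counts are reported for the original acquisitions, so this was fixed
once as a realistic confocal spectral-detector value and drives all
default validation scenes. Droplet cells are disks with a neutral-rich
core (85% neutral share of the Nile Red signal) and a ≈1-pixel polar
rim surrounding the whole cell; droplet-free cells are irregular
(3-lobed) blobs at 10% neutral share; every cell pixel carries a 0.3
EGFP photon fraction (membrane label). Cohort scenes place jittered
cells on a grid with ≥3-pixel gaps. Ground truth (fractions, labels,
per-cell CM/DR/class) is recorded before noise, hence independent of
the noise seed; geometry derives from the cohort seed, noise from the
scene seed.

What the generator does **not** emulate: optical point-spread blur,
z-extent, pigment-cell or gut autofluorescence spectra, detector
afterpulsing, spectral bleed of other fluorophores, and cell-to-cell
biological variability beyond the two morphology classes. Passing tests
therefore demonstrate correctness of the transform, calibration,
unmixing, segmentation and statistics under realistic shot noise — not
robustness to every confounder of real larval imaging.

## Numerical choices and limitations

- Harmonic n = 1 throughout (configurable); higher harmonics spread the
  trajectory but push wide spectra toward the origin.
- Vertex triangle must have area > 1e−6; unmixing refuses collinear
  vertices.
- Validation problem sizes: oracle checks use 100 random 16×16×22
  stacks; forward-mix identities 10⁴ pixels; cohort validation 20 seeds
  × 40 cells at the default budget; null simulations 200–1000
  replicates. These sizes give the quoted rates stable second digits
  while keeping the whole suite under half a minute.
- Touching cells merge; very dim cells (below the Otsu threshold) are
  lost; cells with fewer than `min_size` pixels are dropped — all three
  are deliberate, configurable trade-offs.
- OME-TIFF is the canonical interchange format (channel
  `EmissionWavelength` attributes); plain TIFF plus a configured axis is
  accepted. Pixel coordinates are 0-based (row, col), origin top-left,
  everywhere.
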