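# Methods

## The proximity statistic

Both channels of a two-color field are segmented into objects within a
per-cell cytoplasmic analysis mask (cell outline minus nucleus). Each
object is reduced to its intensity-weighted center of mass (CM) in
micrometres; the pixel grid has its origin at the image's top-left
corner and pixel (r, c) is centered at ((c+0.5)·p, (r+0.5)·p) for pixel
size p. Per cell we compute three Euclidean distance sets:

* red→green — each red CM to the nearest green CM;
* green→green — each green CM to the nearest *other* green CM
  (self excluded);
* red→red — likewise for the red channel (reported for marker-spacing
  comparisons).

Each list is filtered once with Tukey's fences
[Q1 − k·IQR, Q3 + k·IQR], k = 1.5 by default, and the median of the
kept values is the cell's summary. Filtering details that matter:

* Quartiles (and all percentiles in the package) use linear
  interpolation between order statistics — numpy's default, the common
  "type 7" convention.
* The filter is a **single pass**: fences are computed once on the input
  list, never recomputed on the kept values. Iterating fences to a fixed
  point can remove progressively more of a skewed distance distribution;
  the tests pin the single-pass semantics.
* Filtering is applied per cell and per distance list, not pooled across
  cells, and red→green / green→green are filtered separately. Lists of
  length ≤ 2 pass through unchanged (fences from two points are
  meaningless).

Per-cell medians (the analysis unit, typically n = 50 cells per
condition) are summarized as 5/25/50/75/95th percentiles — the box
(25–75) and whiskers (5–95) of a box-whisker plot — and compared across
conditions with the tests below. Cells without green objects are
excluded with a logged reason; cells without red objects still
contribute green→green.

The nearest-neighbor search uses an exhaustive all-pairs scan up to 500
points and a scipy cKD-tree beyond; both return identical minima (the
scan takes the minimum of squared distances before the square root, so
ties are resolved to the same value). Self-exclusion treats a target at
exactly zero distance as "itself"; coincident but distinct points would
be indistinguishable at zero distance anyway.

### The CSR null

For a homogeneous Poisson process of intensity λ per μm², the
nearest-neighbor distance law is P(D ≤ r) = 1 − exp(−λπr²), giving
mean 1/(2√λ) and median √(ln 2/(πλ)). By Slivnyak's theorem the
distance from a process point to its nearest other point follows the
same law, so with uncoupled red puncta and equal treatment the
red→green and green→green medians estimate the same quantity — the
basis of the type-I calibration below.

## The synthetic generator

`CouplingModel` draws fields with known ground truth:

* Cells are discs (default radius 15 μm, a spread-fibroblast scale) laid
  on a jittered grid so they never overlap; the nucleus is a disc of
  `nucleus_fraction` × cell radius (default 0.3), displaced from the
  cell center by `nucleus_offset_frac` (default 0.5) of the available
  slack. The off-center nucleus mirrors spread cells and leaves room for
  large cytoplasmic ROIs. Puncta are placed only in the cytoplasm.
* Green puncta: homogeneous Poisson process on the cytoplasm at
  `green_density` (default 0.2 μm⁻², an endosomal-marker scale: ~100
  puncta in a 15 μm cell). Red puncta: Poisson counts at `red_density`
  (default 0.02 μm⁻², i.e. ~10 PLA puncta per cell).
* The number of coupled red puncta per cell is a Binomial(n_red, f)
  draw — exchangeable, not deterministic rounding, so recovery tests
  average over cells. A coupled red punctum picks a green partner
  uniformly, an offset from the law (`fixed(d)` or `rayleigh(σ)`) and a
  uniform angle; placements outside the cytoplasm are redrawn up to 100
  times, after which the punctum falls back to a uniform position with
  its coupled flag cleared (counted in `n_coupling_fallbacks`).
* Rendering (`RenderSpec`): 0.1 μm pixels, Gaussian spots of σ = 0.15 μm
  sampled at pixel centers, amplitude 100 over background 10, Gaussian
  noise of SD 2 (Poisson and noise-free options available); nuclei as
  blurred filled discs. At these defaults segmented puncta have
  equivalent-circle radii around 0.2–0.3 μm. All intensities are clipped
  at zero.
* Determinism: every draw comes from one `numpy` Generator seeded by the
  model; identical parameters and seed give bit-identical fields.

What the generator does **not** emulate: 3-D structure, non-disc cell
shapes, photobleaching, chromatic shift, cell motion, spatially varying
background, and clustered (non-Poisson) marker organization. Passing
tests therefore demonstrate correctness of the measurement chain on an
idealized field, not robustness to every property of real images.

## Segmentation

Puncta are thresholded with Otsu's method on a 256-bin histogram over
the masked min–max range, maximizing the between-class variance with
ties broken to the lowest maximizing split; foreground is strictly
`intensity > threshold`. Connected components use 8-connectivity (the
ImageJ particle-analysis default) with a minimum size of 4 px
(configurable, maximum optional), and CMs are intensity-weighted
(a binary-centroid option exists). Otsu is computed per image, per
channel, within the cell's analysis region; a shared-threshold mode
serves the pixel-based colocalization stage. Objects are clipped to the
analysis mask, which shifts the CM of puncta straddling the mask edge
inward — sub-pixel CM accuracy holds for spots clear of boundaries and
of other spots (> 4σ separation).

Nucleus segmentation is Otsu + hole filling + components + minimum
area; touching nuclei count as one (no watershed, by scope).

**Whole-image particle counting** (`count_particles`, the PLA-per-cell
counter) does *not* default to Otsu: with a realistic PLA load the
foreground can be well under 0.1% of pixels, where the between-class
variance of splitting the background noise rivals that of the true
spot/background split and the Otsu threshold collapses into the noise.
The default is a robust background rule — median + 6·(1.4826·MAD) of
the image — which is insensitive to arbitrarily sparse foreground;
`threshold_method="otsu"` restores the histogram method. A constant
image yields count 0 with a warning.

## Pixel-based colocalization

Square ROIs of a requested area (225 or 56.25 μm² in the motivating
analyses) are placed fully inside the cytoplasm by seeded rejection over
the cell's bounding box (first fitting candidate wins; placement is
logged and reproducible). Pearson's r is the sample correlation of
paired pixels in the ROI. Manders' coefficients are the thresholded
variant: M1 = Σ ch1 over pixels above both thresholds / Σ ch1 over
pixels with ch1 > thr1, and symmetrically M2 — this keeps both in
[0, 1]; thresholds of 0 give the unthresholded variant. One threshold
per antibody group is obtained by pooling all ROI pixels of the group
into a single 256-bin histogram and applying Otsu, so every ROI stained
with the same antibody is thresholded identically.

## Quantification

PLA signals per cell = whole-image particle count / nucleus count;
images with zero nuclei are excluded with a warning. Condition means are
taken over images (six in the emulated design), folds are relative to a
control condition (≡ 1), and SDs are over per-image ratios. Time-lapse
traces are background-subtracted (scalar or per-frame background) and
divided by the mean of the first three pre-stimulation frames, so the
baseline mean of the relative trace is exactly 1 and the operation is
idempotent. QC excludes cells whose ROI area drops below 0.7 of its
initial value at any frame (an operationalization of "shrinking or
detachment"); the fraction is configurable.

## Statistics

Welch's t (unequal variances, Welch–Satterthwaite df) and the paired t
delegate to scipy. The paired test needs a zero-variance convention:
identical samples give t = 0, p = 1; a constant nonzero difference is
maximally sign-consistent, so the sign-test bound p = 2^(1−n) is
reported with a `zero_variance` flag rather than dividing by zero.
"Bonferroni/Dunn" (StatView's name) is implemented as pairwise t-tests
on the pooled within-group mean square (df = N − k) with p-values
multiplied by the number of comparisons, capped at 1; pairwise Welch +
Bonferroni is available as an option.

### Calibration and power (what the validation experiments show)

* With f = 0 and λ_green = 1 μm⁻² the pooled red→green distances match
  the analytic CSR law to KS < 0.02 and the pooled median is within ~1%
  of √(ln 2/π) ≈ 0.4697 μm (20 μm cells; the law ignores boundary
  truncation, which the large cells keep negligible).
* Full-pipeline recovery: f = 1 with a fixed 0.30 μm offset, 50 rendered
  cells at default settings, gives a condition median within one pixel
  (±0.1 μm) of 0.30 μm.
* Discrimination: f = 0.8, offset 0.3 μm, marker density set so the CSR
  median is 0.9 μm (λ = ln 2/(0.81π) ≈ 0.272 μm⁻²): a one-sided Welch
  test on per-cell medians detects red→green < green→green at α = 0.01
  in ≈ 100% of 100 fifty-cell conditions; at f = 0 the same comparison
  fires in ≤ 1%.
* Type-I calibration of Welch's test uses per-cell median red→green
  from one simulated null condition and green→green from an
  *independently* simulated one (equal red/green densities, 50 cells
  each): the rejection rate over 1000 repetitions is ≈ 5%. Within a
  single cell the two medians share the green pattern and are positively
  correlated, making the same-cell comparison mildly conservative
  (≈ 4% measured) — which is why the independent design is used to
  check the nominal level.
* Bonferroni familywise error on all-null 4-group data is ≈ 0.04 ≤ α,
  as the inequality guarantees.

### Problem sizes

The reference experiments use 50-cell conditions (5–50 cells per
rendered field), 100 conditions for the discrimination rates, 1000
repetitions for the Welch calibration and 5000 for the familywise-error
simulation; rendered checks use 0.1 μm pixels on fields of roughly
500–900 px per side. These sizes put Monte-Carlo error comfortably below
the asserted tolerances while keeping a full run in the minutes range.

## Known limitations

* Through the rendered chain at marker densities where spots merge
  (nearest-neighbor spacing below ~4σ), merging removes the shortest
  green→green distances and biases that scale upward, so the
  *image-level* red→green vs green→green comparison is anticonservative
  under the null even though the point-level comparison is calibrated.
  Comparisons of the same readout across conditions (the primary design)
  share this bias and are unaffected. No watershed splitting is
  attempted, by scope.
* Whole-image Otsu counting of a *blank* noisy image produces spurious
  foreground; the robust default handles this, but Otsu mode does not.
* The generator's densities, PSF width and pixel size are calibrated to
  reproduce printed length scales of confocal puncta analyses, not any
  specific acquisition; pixel size must always be supplied by metadata
  or config, never guessed.
* ROI placement needs the square to fit in the cytoplasm: a 15 μm square
  requires spread cells (≳ 20 μm radius discs with an off-center
  nucleus); infeasible cells raise an error and are skipped by the
  pipeline with a log entry.
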