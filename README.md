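# punctaprox

Object-based proximity analysis for sparse fluorescent puncta.

## The problem

Proximity ligation assays (PLA) and similar punctate readouts produce a
handful of discrete, diffraction-limited spots per cell — for example
puncta marking an oxidized phosphatase — which one wants to localize
relative to a much denser organelle marker (RAB5, EEA1, clathrin, NOX
subunits, …). Pixel-based colocalization coefficients (Pearson's r,
Manders' M1/M2) are poorly suited to this regime: a punctum covering a
few dozen pixels barely moves a pixel-wise correlation even when it is
reproducibly adjacent to a marker structure.

The object-based alternative implemented here segments both channels
into objects, reduces each object to its intensity-weighted center of
mass (CM), and measures, per cell,

* **red→green**: the distance from each sparse (red) punctum's CM to the
  nearest marker (green) CM, and
* **green→green**: each marker punctum's distance to its nearest *other*
  marker punctum — the internal spacing scale against which red→green
  proximity is judged.

Outliers are removed per cell with Tukey's fences
(`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`), the per-cell **medians** of the
remaining distances are the analysis unit (typically n = 50 cells per
condition), and conditions are compared with Welch's t-test, paired
t-tests or one-way ANOVA with a Bonferroni/Dunn post-hoc. Under complete
spatial randomness (CSR) the nearest-neighbor distance to a marker of
density λ (μm⁻²) follows

    P(D ≤ r) = 1 − exp(−λπr²),   median = √(ln 2 / (πλ)),  mean = 1/(2√λ),

which the package exposes as the analytic null (`csr_reference`).

Because real microscopy data of this kind is rarely deposited, the
package includes a first-class synthetic generator: fields of disc cells
with off-center nuclei, marker puncta as a Poisson process on the
cytoplasm, and a fraction *f* of red puncta placed at a controlled
offset from a marker punctum, rendered to noisy multi-channel images
with full ground truth. Every stage — Otsu segmentation, CM extraction,
nearest-neighbor distances, Tukey filtering, per-cell medians, PLA
counts per nucleus, time-lapse normalization and the statistics — is
verifiable against that ground truth.

## Worked example

`examples/coupled_field.yaml`:

```yaml
n_fields: 10
model:
  cell_count: 5
  cell_radius_um: 10.0
  green_density: 0.2      # marker puncta per um^2 of cytoplasm
  red_density: 0.02       # PLA puncta per um^2
  coupling_fraction: 0.8
  offset_law: {fixed: 0.3}
proximity:
  n_cells: 50
```

```
punctaprox run --config examples/coupled_field.yaml --seed 17 --out out/
```

simulates 50 cells in which 80% of red puncta sit exactly 0.3 μm from a
marker punctum, renders them (0.1 μm pixels, Gaussian spots, noise),
segments both channels per cell and prints:

```json
{
  "red_to_green": {
    "n_cells": 50,
    "percentiles": {
      "p5": 0.29083037118406746,
      "p25": 0.2975174284824499,
      "p50": 0.30210554035936055,
      "p75": 0.3088681506008162,
      "p95": 0.7834002990705399
    }
  },
  "green_to_green": {
    "n_cells": 50,
    "percentiles": {
      "p5": 1.0902890400483272,
      "p25": 1.1651176484925656,
      "p50": 1.2475233052651329,
      "p75": 1.3171559005676734,
      "p95": 1.460770801307599
    }
  },
  "welch_red_vs_green_spacing": {
    "t": -27.564407715425443,
    "df": 80.76440918936494,
    "p_value": 7.683549129643802e-43
  }
}
```

The condition median red→green distance (p50 = 0.302 μm) recovers the
imposed 0.3 μm offset to well within one pixel, and sits far below the
marker's own internal spacing (1.25 μm median), exactly the signature an
associated punctum population produces. The percentiles are the box
(25–75) and whiskers (5–95) of the usual box-whisker presentation.

Other subcommands: `punctaprox simulate | segment | proximity | coloc |
quantify | stats` operate on TIFF fields, objects CSVs and count tables;
run each with `--help`.

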