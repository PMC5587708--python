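"""Synthetic two-channel puncta fields with known ground truth.

Emulates the statistical structure that object-based proximity analysis
of PLA puncta assumes: fields of several cells, each a disc with an
off-center nuclear disc; a dense "green" marker channel (endosomal
markers such as RAB5/EEA1) as a homogeneous Poisson process on the
cytoplasm; and a sparse "red" channel (PLA signals) in which a fraction
``f`` of puncta sit at a controlled offset from a green punctum while the
rest are completely spatially random. Fields can be rendered to noisy
multi-channel images so that the full segmentation → proximity chain is
testable against ground truth, and helpers simulate PLA-count panels and
post-stimulation time-lapse traces.

Defaults are calibrated to confocal-scale acquisitions: 0.1 μm pixels,
0.15 μm Gaussian spot width (PLA-like puncta threshold to roughly
0.4–0.6 μm equivalent radii), fibroblast-like cells of 10–15 μm radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .segmentation import CellRegion, ChannelImage

__all__ = [
    "FixedOffset",
    "RayleighOffset",
    "CouplingModel",
    "RenderSpec",
    "CellTruth",
    "GroundTruth",
    "FieldImage",
    "simulate_point_pattern",
    "render_field",
    "regions_from_truth",
    "simulate_pla_panel",
    "PlaPanel",
    "PlaField",
    "simulate_timelapse",
]


@dataclass(frozen=True)
class FixedOffset:
    """Coupled red puncta sit at exactly d_um from their green partner."""

    d_um: float


@dataclass(frozen=True)
class RayleighOffset:
    """Coupled offsets are Rayleigh-distributed with scale sigma_um."""

    sigma_um: float


@dataclass(frozen=True)
class CouplingModel:
    """Ground-truth parameters of the two-channel point process.

    nucleus_fraction is the nucleus radius as a fraction of the cell
    radius; the nucleus center is displaced from the cell center by
    nucleus_offset_frac of the available slack so that large cytoplasmic
    ROIs can fit, as they do in spread fibroblasts. Densities are puncta
    per μm² of cytoplasm (cell minus nucleus). coupling_fraction is the
    probability that a red punctum is tied to a green one.
    """

    cell_count: int = 10
    cell_radius_um: float = 15.0
    nucleus_fraction: float = 0.3
    nucleus_offset_frac: float = 0.5
    green_density: float = 0.2
    red_density: float = 0.02
    coupling_fraction: float = 0.0
    offset_law: FixedOffset | RayleighOffset = FixedOffset(0.3)
    seed: int = 0
    cell_margin_um: float = 2.0

    def __post_init__(self) -> None:
        if self.cell_count < 1:
            raise ValueError("cell_count must be >= 1")
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ValueError("coupling_fraction must be in [0, 1]")
        if self.green_density <= 0 or self.red_density <= 0:
            raise ValueError("densities must be positive")
        if not 0.0 <= self.nucleus_fraction < 1.0:
            raise ValueError(
                "degenerate geometry: nucleus must not cover the cell"
            )
        if not 0.0 <= self.nucleus_offset_frac <= 1.0:
            raise ValueError("nucleus_offset_frac must be in [0, 1]")


@dataclass(frozen=True)
class RenderSpec:
    """How a point pattern becomes a multi-channel image."""

    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] | None = None  # (rows, cols); derived if None
    spot_sigma_um: float = 0.15
    spot_amplitude: float = 100.0
    background: float = 10.0
    noise_model: str = "gaussian"  # "none" | "gaussian" | "poisson"
    gaussian_sd: float = 2.0
    nucleus_amplitude: float = 80.0
    nucleus_blur_um: float = 0.3

    def __post_init__(self) -> None:
        if self.spot_sigma_um <= 0:
            raise ValueError("spot_sigma_um must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class CellTruth:
    """One cell's geometry and true point lists (μm, image coordinates)."""

    cell_id: int
    cell_center: np.ndarray  # (x, y)
    cell_radius_um: float
    nucleus_center: np.ndarray
    nucleus_radius_um: float
    red: np.ndarray  # (n_red, 2)
    green: np.ndarray  # (n_green, 2)
    coupled: np.ndarray  # bool, per red point
    partner: np.ndarray  # green index per red point, -1 if uncoupled

    def in_cytoplasm(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        d_cell = np.hypot(*(p - self.cell_center).T)
        d_nuc = np.hypot(*(p - self.nucleus_center).T)
        return (d_cell <= self.cell_radius_um) & (d_nuc > self.nucleus_radius_um)


@dataclass
class GroundTruth:
    """A simulated field: cells plus true red/green point patterns."""

    model: CouplingModel
    cells: list[CellTruth]
    field_size_um: tuple[float, float]  # (width, height)
    n_coupling_fallbacks: int = 0

    def all_points(self, channel: str) -> np.ndarray:
        arrs = [getattr(c, channel) for c in self.cells]
        return np.vstack([a for a in arrs if len(a)]) if any(len(a) for a in arrs) else np.empty((0, 2))

    def suggested_shape(self, pixel_size_um: float) -> tuple[int, int]:
        w, h = self.field_size_um
        return (int(math.ceil(h / pixel_size_um)), int(math.ceil(w / pixel_size_um)))


@dataclass
class FieldImage:
    """Rendered multi-channel field (channel label → ChannelImage)."""

    channels: dict[str, ChannelImage]
    pixel_size_um: float

    def __getitem__(self, label: str) -> ChannelImage:
        return self.channels[label]


def _layout_cells(model: CouplingModel, rng: np.random.Generator):
    """Place cells on a jittered grid; cells never overlap."""
    n = model.cell_count
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    spacing = 2.0 * (model.cell_radius_um + model.cell_margin_um)
    field = (ncols * spacing, nrows * spacing)
    centers = []
    jmax = model.cell_margin_um / 2.0
    for k in range(n):
        i, j = divmod(k, ncols)
        base = np.array([(j + 0.5) * spacing, (i + 0.5) * spacing])
        centers.append(base + rng.uniform(-jmax, jmax, size=2))
    return centers, field


def _sample_cytoplasm(
    n: int,
    cell_center: np.ndarray,
    r_cell: float,
    nuc_center: np.ndarray,
    r_nuc: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform points on the cell disc minus the nucleus disc."""
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        r = r_cell * np.sqrt(rng.uniform(size=m))
        th = rng.uniform(0, 2 * math.pi, size=m)
        pts = cell_center + np.column_stack([r * np.cos(th), r * np.sin(th)])
        ok = np.hypot(*(pts - nuc_center).T) > r_nuc
        take = min(int(ok.sum()), n - got)
        out[got : got + take] = pts[ok][:take]
        got += take
    return out


def _draw_offset(law: FixedOffset | RayleighOffset, rng: np.random.Generator) -> float:
    if isinstance(law, FixedOffset):
        return law.d_um
    return float(rng.rayleigh(law.sigma_um))


_COUPLING_ATTEMPTS = 100


def simulate_point_pattern(model: CouplingModel) -> GroundTruth:
    """Draw a field of cells with green and (partially coupled) red puncta.

    Per cell: green puncta are a homogeneous Poisson process on the
    cytoplasm at ``green_density``; red counts are Poisson at
    ``red_density`` and each red punctum is coupled with probability
    ``coupling_fraction`` (a Binomial draw over the cell's reds). A
    coupled red is placed at an offset drawn from ``offset_law`` at a
    uniform angle from a uniformly chosen green punctum, redrawing up to
    100 times if it lands outside the cytoplasm; after that it falls back
    to a uniform position with the coupled flag cleared (counted in
    ``n_coupling_fallbacks``). Identical model (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(model.seed)
    centers, field_size = _layout_cells(model, rng)
    r_cell = model.cell_radius_um
    r_nuc = model.nucleus_fraction * r_cell
    cyto_area = math.pi * (r_cell**2 - r_nuc**2)
    if cyto_area <= 0:
        raise ValueError("degenerate geometry: empty cytoplasm")
    cells: list[CellTruth] = []
    fallbacks = 0
    for cid, c in enumerate(centers):
        # off-center nucleus, fully inside the cell
        slack = (r_cell - r_nuc) * model.nucleus_offset_frac
        th = rng.uniform(0, 2 * math.pi)
        nuc_center = c + slack * np.array([math.cos(th), math.sin(th)])
        n_green = int(rng.poisson(model.green_density * cyto_area))
        green = _sample_cytoplasm(n_green, c, r_cell, nuc_center, r_nuc, rng)
        n_red = int(rng.poisson(model.red_density * cyto_area))
        n_coupled = int(rng.binomial(n_red, model.coupling_fraction)) if n_red else 0
        if n_green == 0:
            n_coupled = 0
        coupled_flags = np.zeros(n_red, dtype=bool)
        coupled_flags[:n_coupled] = True
        red = np.empty((n_red, 2))
        partner = np.full(n_red, -1, dtype=int)
        cell = CellTruth(
            cid, np.asarray(c), r_cell, nuc_center, r_nuc,
            red, green, coupled_flags, partner,
        )
        for i in range(n_red):
            if coupled_flags[i]:
                placed = False
                for _ in range(_COUPLING_ATTEMPTS):
                    g = int(rng.integers(n_green))
                    d = _draw_offset(model.offset_law, rng)
                    a = rng.uniform(0, 2 * math.pi)
                    pos = green[g] + d * np.array([math.cos(a), math.sin(a)])
                    if cell.in_cytoplasm(pos)[0]:
                        red[i] = pos
                        partner[i] = g
                        placed = True
                        break
                if not placed:
                    red[i] = _sample_cytoplasm(1, c, r_cell, nuc_center, r_nuc, rng)[0]
                    coupled_flags[i] = False
                    fallbacks += 1
            else:
                red[i] = _sample_cytoplasm(1, c, r_cell, nuc_center, r_nuc, rng)[0]
        cells.append(cell)
    return GroundTruth(model, cells, field_size, n_coupling_fallbacks=fallbacks)


def _stamp_spots(
    img: np.ndarray, points_um: np.ndarray, sigma_um: float, amplitude: float, p: float
) -> None:
    """Add Gaussian spots sampled at pixel centers, in place."""
    if len(points_um) == 0:
        return
    sig = sigma_um / p
    w = int(math.ceil(6 * sig))
    H, W = img.shape
    for x_um, y_um in points_um:
        # pixel-center coordinates of the point
        cx, cy = x_um / p - 0.5, y_um / p - 0.5
        r0, r1 = max(0, int(cy) - w), min(H, int(cy) + w + 2)
        c0, c1 = max(0, int(cx) - w), min(W, int(cx) + w + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1) - cy
        cc = np.arange(c0, c1) - cx
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -(rr[:, None] ** 2 + cc[None, :] ** 2) / (2 * sig**2)
        )


def _disc_mask(shape, center_um, radius_um, p) -> np.ndarray:
    rows = (np.arange(shape[0]) + 0.5) * p
    cols = (np.arange(shape[1]) + 0.5) * p
    return (rows[:, None] - center_um[1]) ** 2 + (
        cols[None, :] - center_um[0]
    ) ** 2 <= radius_um**2


def render_field(
    truth: GroundTruth, spec: RenderSpec = RenderSpec(), seed: int = 0
) -> FieldImage:
    """Render a field to nuclei / red / green channels.

    Nuclei are filled blurred discs; puncta are Gaussian spots sampled at
    pixel centers; background and the configured noise are added last and
    intensities clipped at zero. Raises if any true point falls outside
    the image, listing the offenders.
    """
    p = spec.pixel_size_um
    shape = spec.image_shape or truth.suggested_shape(p)
    w_um, h_um = shape[1] * p, shape[0] * p
    offenders = [
        (c.cell_id, ch, i, tuple(pt))
        for c in truth.cells
        for ch in ("red", "green")
        for i, pt in enumerate(getattr(c, ch))
        if not (0 <= pt[0] < w_um and 0 <= pt[1] < h_um)
    ]
    if offenders:
        raise ValueError(f"points outside image bounds: {offenders[:10]}")
    rng = np.random.default_rng(seed)
    nuc = np.zeros(shape)
    for c in truth.cells:
        nuc[_disc_mask(shape, c.nucleus_center, c.nucleus_radius_um, p)] = (
            spec.nucleus_amplitude
        )
    nuc = gaussian_filter(nuc, spec.nucleus_blur_um / p)
    red = np.zeros(shape)
    green = np.zeros(shape)
    _stamp_spots(red, truth.all_points("red"), spec.spot_sigma_um, spec.spot_amplitude, p)
    _stamp_spots(green, truth.all_points("green"), spec.spot_sigma_um, spec.spot_amplitude, p)
    channels = {}
    for label, img in (("nuclei", nuc), ("red", red), ("green", green)):
        img = img + spec.background
        if spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, spec.gaussian_sd, size=shape)
        elif spec.noise_model == "poisson":
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        channels[label] = ChannelImage(np.clip(img, 0.0, None), p, label)
    return FieldImage(channels, p)


def regions_from_truth(
    truth: GroundTruth, pixel_size_um: float, image_shape: tuple[int, int] | None = None
) -> list[CellRegion]:
    """Rasterize the true cell/nucleus geometry into per-cell regions.

    Stands in for the manually drawn cell-shape ROIs and DAPI nucleus
    masks of a real analysis.
    """
    shape = image_shape or truth.suggested_shape(pixel_size_um)
    regions = []
    for c in truth.cells:
        cell = _disc_mask(shape, c.cell_center, c.cell_radius_um, pixel_size_um)
        nuc = _disc_mask(shape, c.nucleus_center, c.nucleus_radius_um, pixel_size_um)
        regions.append(CellRegion(c.cell_id, cell, nuc & cell))
    return regions


@dataclass
class PlaField:
    condition: str
    image_index: int
    truth: GroundTruth
    image: FieldImage | None
    true_count: int  # total red puncta in the field


@dataclass
class PlaPanel:
    fields: list[PlaField]

    def true_counts(self, condition: str) -> list[int]:
        return [f.true_count for f in self.fields if f.condition == condition]


def simulate_pla_panel(
    conditions: Sequence[tuple[str, float]],
    n_images: int,
    cells_per_image: int,
    seed: int = 0,
    *,
    cell_radius_um: float = 10.0,
    render_spec: RenderSpec | None = None,
    render: bool = True,
) -> PlaPanel:
    """Simulate a PLA quantification panel with known per-cell means.

    Per condition ``(name, puncta_per_cell_mean)``, ``n_images`` fields
    are drawn whose true red-puncta counts are Poisson with the stated
    per-cell mean (so a field's total is Poisson with mean
    cells_per_image × per-cell mean). Fields carry no green channel
    signal; nuclei are rendered for nucleus counting.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if render_spec is None:
        render_spec = RenderSpec()
    rng = np.random.default_rng(seed)
    fields = []
    for name, mean in conditions:
        if mean < 0:
            raise ValueError("puncta_per_cell_mean must be >= 0")
        for idx in range(n_images):
            model = CouplingModel(
                cell_count=cells_per_image,
                cell_radius_um=cell_radius_um,
                # density placeholder; red counts are drawn explicitly below
                red_density=1e-9,
                green_density=1e-9,
                seed=int(rng.integers(2**31)),
            )
            truth = simulate_point_pattern(model)
            cell_rng = np.random.default_rng(int(rng.integers(2**31)))
            total = 0
            for cell in truth.cells:
                n = int(cell_rng.poisson(mean))
                cell.red = _sample_cytoplasm(
                    n, cell.cell_center, cell.cell_radius_um,
                    cell.nucleus_center, cell.nucleus_radius_um, cell_rng,
                )
                cell.green = np.empty((0, 2))
                cell.coupled = np.zeros(n, dtype=bool)
                cell.partner = np.full(n, -1, dtype=int)
                total += n
            image = (
                render_field(truth, render_spec, seed=int(rng.integers(2**31)))
                if render
                else None
            )
            fields.append(PlaField(name, idx, truth, image, total))
    return PlaPanel(fields)


def simulate_timelapse(
    baseline: float,
    fold_rise: float,
    rise_frame: int,
    n_frames: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_cells: int = 7,
) -> np.ndarray:
    """Per-cell raw intensity traces around a stimulation frame.

    Frames are 1-based; stimulation occurs after the third scan, so
    ``rise_frame`` (the first elevated frame) must be >= 4. Frames before
    ``rise_frame`` fluctuate around ``baseline``, later frames around
    ``baseline * fold_rise``. Returns an (n_cells, n_frames) array.
    """
    if rise_frame < 4:
        raise ValueError("rise_frame must be >= 4 (stimulation after third scan)")
    if n_frames < rise_frame:
        raise ValueError("n_frames must be >= rise_frame")
    rng = np.random.default_rng(seed)
    level = np.full(n_frames, float(baseline))
    level[rise_frame - 1 :] = baseline * fold_rise
    traces = np.tile(level, (n_cells, 1))
    if noise_sd > 0:
        traces = traces + rng.normal(0.0, noise_sd, size=traces.shape)
    return traces
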