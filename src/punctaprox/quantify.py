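"""Scalar readouts: PLA signals per cell and relative time-lapse traces.

PLA quantification divides the whole-image particle count by the nucleus
count, averages images per condition (typically six) and normalizes to an
unstimulated control (set to 1). Time-lapse traces (e.g. an H2O2 sensor
after growth-factor addition) are background-subtracted and expressed
relative to the mean of the first three pre-stimulation frames; cells
that shrink or detach are excluded by an area-based QC rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlaImageCount",
    "PlaQuantification",
    "TimelapseTrace",
    "pla_per_cell",
    "relative_timelapse",
    "qc_exclude",
]


@dataclass(frozen=True)
class PlaImageCount:
    """Raw counts for one image: particles (PLA puncta) and nuclei."""

    image_id: str
    condition: str
    particle_count: int
    nucleus_count: int

    @property
    def signals_per_cell(self) -> float:
        return self.particle_count / self.nucleus_count


@dataclass
class PlaQuantification:
    """Per-condition PLA-per-cell means, SDs and fold changes vs control."""

    control: str
    per_image: list[PlaImageCount]
    mean_per_condition: dict[str, float]
    sd_per_condition: dict[str, float]
    fold_change: dict[str, float]
    excluded_images: list[str] = field(default_factory=list)


@dataclass
class TimelapseTrace:
    """Background-subtracted trace relative to the pre-stimulation baseline."""

    cell_id: str
    raw: np.ndarray
    relative: np.ndarray
    n_baseline: int
    qc_flag: str = ""


def pla_per_cell(
    images: list[PlaImageCount], control: str
) -> PlaQuantification:
    """Aggregate per-image PLA-signals-per-cell into condition fold changes.

    Images with zero nuclei are excluded with a warning. The control
    condition's fold change is 1 by construction; a missing control is an
    error. SDs are over the per-image ratios (ddof=1; 0 for a single
    image).
    """
    usable: list[PlaImageCount] = []
    excluded = []
    for im in images:
        if im.nucleus_count < 1:
            warnings.warn(f"image {im.image_id}: zero nuclei, excluded", stacklevel=2)
            excluded.append(im.image_id)
        else:
            usable.append(im)
    conditions = {im.condition for im in usable}
    if control not in conditions:
        raise ValueError(f"control condition {control!r} missing")
    means, sds = {}, {}
    for cond in sorted(conditions):
        ratios = np.array([im.signals_per_cell for im in usable if im.condition == cond])
        means[cond] = float(ratios.mean())
        sds[cond] = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    ctrl_mean = means[control]
    if ctrl_mean <= 0:
        raise ValueError("control mean is zero; fold changes undefined")
    fold = {cond: m / ctrl_mean for cond, m in means.items()}
    return PlaQuantification(control, usable, means, sds, fold, excluded)


def relative_timelapse(
    trace, background: float | np.ndarray = 0.0, n_baseline: int = 3, cell_id: str = ""
) -> TimelapseTrace:
    """Normalize a raw intensity trace to its pre-stimulation baseline.

    Subtracts ``background`` (scalar or per-frame) and divides by the
    mean of the first ``n_baseline`` frames, so the baseline mean of the
    relative trace is exactly 1. Applying it to an already-relative trace
    returns it unchanged. A nonpositive baseline after background
    subtraction is an error.
    """
    raw = np.asarray(trace, dtype=float)
    if raw.ndim != 1:
        raise ValueError("trace must be 1D")
    if raw.size < n_baseline:
        raise ValueError(f"need at least {n_baseline} frames")
    corrected = raw - np.asarray(background, dtype=float)
    baseline = corrected[:n_baseline].mean()
    if baseline <= 0:
        raise ValueError("nonpositive baseline after background subtraction")
    return TimelapseTrace(cell_id, raw, corrected / baseline, n_baseline)


def qc_exclude(
    traces: list[TimelapseTrace],
    area_series: dict[str, np.ndarray],
    min_area_fraction: float = 0.7,
) -> tuple[list[TimelapseTrace], list[TimelapseTrace]]:
    """Exclude shrinking/detaching cells by their ROI area over time.

    A cell is excluded when its area at any frame drops below
    ``min_area_fraction`` of its initial area (detachment shows up as
    area collapsing toward zero). Returns (included, excluded); excluded
    traces carry the reason in ``qc_flag``.
    """
    included, excluded = [], []
    for tr in traces:
        areas = np.asarray(area_series[tr.cell_id], dtype=float)
        if areas.size == 0 or areas[0] <= 0:
            tr.qc_flag = "invalid area series"
            excluded.append(tr)
            continue
        frac = areas / areas[0]
        if frac.min() < min_area_fraction:
            tr.qc_flag = (
                f"shrinking/detached: area fell to {frac.min():.2f} of initial"
            )
            excluded.append(tr)
        else:
            included.append(tr)
    return included, excluded
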