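"""Object-based nearest-neighbor proximity analysis.

The core readout: per cell, the Euclidean distance from each red-object
center of mass (e.g. a PLA punctum marking oxidized SHP2) to the nearest
green-object center of mass (an organelle marker such as RAB5 or EEA1),
judged against the internal green-to-green spacing of the marker itself.
Tukey's fences remove outlier distances per cell; the per-cell medians of
the remaining distances are the unit subjected to statistics, typically
over n = 50 cells per condition.

All distances are in micrometres. Percentiles throughout use linear
interpolation between order statistics ("type 7", numpy's default), the
convention also used for the Tukey quartiles and box-whisker summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .segmentation import PunctaObject

__all__ = [
    "ProximityRecord",
    "ConditionSummary",
    "nn_distances",
    "tukey_filter",
    "cell_proximity",
    "summarize_condition",
    "csr_reference",
]

#: above this many points a KD-tree replaces the all-pairs scan
KDTREE_CUTOFF = 500


class CsrReference(NamedTuple):
    mean_nn_um: float
    median_nn_um: float


@dataclass
class ProximityRecord:
    """Per-cell nearest-neighbor distance sets and their medians.

    Distance lists are stored both raw and after single-pass Tukey
    filtering; medians are computed on the kept values only. A cell that
    cannot support a readout (no green objects, or fewer than two greens
    for the self-distance) is flagged excluded rather than raising.
    """

    cell_id: int
    n_red: int
    n_green: int
    red_to_green_um: np.ndarray
    green_to_green_um: np.ndarray
    red_to_red_um: np.ndarray
    removed_outliers: dict = field(default_factory=dict)
    median_red_to_green_um: float = math.nan
    median_green_to_green_um: float = math.nan
    median_red_to_red_um: float = math.nan
    excluded: bool = False
    excluded_reason: str = ""

    @property
    def n_outliers_removed(self) -> int:
        return sum(len(v) for v in self.removed_outliers.values())


@dataclass
class ConditionSummary:
    """Per-condition collection of per-cell medians with percentiles.

    `percentiles` holds the 5th/25th/50th/75th/95th percentiles of the
    per-cell medians — the box (25–75) and whiskers (5–95) of the usual
    box-whisker presentation.
    """

    condition: str
    metric: str
    cell_medians_um: np.ndarray
    percentiles: tuple[float, float, float, float, float]
    n_cells: int

    def __post_init__(self) -> None:
        p = self.percentiles
        if any(p[i] > p[i + 1] for i in range(4)):
            raise ValueError("percentiles must be nondecreasing")


def _as_points(points) -> np.ndarray:
    if len(points) and isinstance(points[0], PunctaObject):
        pts = np.array([[o.cm_x_um, o.cm_y_um] for o in points], dtype=float)
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return pts


def nn_distances(
    query_points, target_points, exclude_self: bool = False
) -> np.ndarray:
    """Distance from each query point to its nearest target point (μm).

    With ``exclude_self`` and identical query/target sets, each point's
    distance to the nearest *other* point is returned. Output order
    follows the query order. Uses an exhaustive scan for small inputs and
    a KD-tree beyond KDTREE_CUTOFF points; both return the same minima.
    """
    q = _as_points(query_points)
    t = _as_points(target_points)
    min_targets = 2 if exclude_self else 1
    if len(t) < min_targets:
        raise ValueError("no target objects in cell")
    if q.shape[0] == 0:
        return np.empty(0)
    if max(len(q), len(t)) <= KDTREE_CUTOFF:
        d2 = (q[:, None, 0] - t[None, :, 0]) ** 2 + (q[:, None, 1] - t[None, :, 1]) ** 2
        if exclude_self:
            # a query at zero squared distance from a target is "itself"
            d2[d2 == 0.0] = np.inf
        return np.sqrt(d2.min(axis=1))
    tree = cKDTree(t)
    k = 2 if exclude_self else 1
    dist, _ = tree.query(q, k=k)
    if exclude_self:
        dist = np.where(dist[:, 0] == 0.0, dist[:, 1], dist[:, 0])
    return np.asarray(dist, dtype=float).reshape(-1)


def tukey_filter(
    distances: Sequence[float], k: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Tukey-fence outlier removal.

    Removes values outside [Q1 - k*IQR, Q3 + k*IQR], quartiles by linear
    interpolation of order statistics. Fences are computed once on the
    input; they are NOT recomputed on the kept values. Lists of length
    <= 2 pass through unchanged. Returns (kept values, removed indices).
    """
    values = np.asarray(distances, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("distances must be a non-empty 1D sequence")
    if values.size <= 2:
        return values.copy(), np.empty(0, dtype=int)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], np.nonzero(~keep)[0]


def cell_proximity(
    red, green, cell_id: int | None = None, k: float = 1.5, filter_outliers: bool = True
) -> ProximityRecord:
    """Assemble a cell's red→green, green→green and red→red distances.

    Outlier filtering (Tukey fences, multiplier ``k``) is applied to each
    list separately, per cell, before medians are taken. Cells with no
    green objects are returned flagged ``excluded`` instead of raising;
    cells with no red objects still contribute green→green.
    """
    red_pts = _as_points(red)
    green_pts = _as_points(green)
    if cell_id is None:
        ids = {o.cell_id for o in list(red) + list(green) if isinstance(o, PunctaObject)}
        if len(ids) > 1:
            raise ValueError(f"objects from multiple cells: {sorted(ids)}")
        cell_id = ids.pop() if ids else -1
    rec = ProximityRecord(
        cell_id=cell_id,
        n_red=len(red_pts),
        n_green=len(green_pts),
        red_to_green_um=np.empty(0),
        green_to_green_um=np.empty(0),
        red_to_red_um=np.empty(0),
    )
    if len(green_pts) == 0:
        rec.excluded = True
        rec.excluded_reason = "no green objects"
        return rec

    def _finish(key: str, dists: np.ndarray) -> float:
        if filter_outliers and dists.size:
            kept, removed = tukey_filter(dists, k=k)
        else:
            kept, removed = dists, np.empty(0, dtype=int)
        rec.removed_outliers[key] = removed
        return float(np.median(kept)) if kept.size else math.nan

    if len(red_pts) >= 1:
        rec.red_to_green_um = nn_distances(red_pts, green_pts)
        rec.median_red_to_green_um = _finish("red_to_green", rec.red_to_green_um)
    if len(green_pts) >= 2:
        rec.green_to_green_um = nn_distances(green_pts, green_pts, exclude_self=True)
        rec.median_green_to_green_um = _finish("green_to_green", rec.green_to_green_um)
    if len(red_pts) >= 2:
        rec.red_to_red_um = nn_distances(red_pts, red_pts, exclude_self=True)
        rec.median_red_to_red_um = _finish("red_to_red", rec.red_to_red_um)
    return rec


def summarize_condition(
    records: Sequence[ProximityRecord],
    n_cells: int = 50,
    metric: str = "red_to_green",
    condition: str = "",
) -> ConditionSummary:
    """Collect per-cell medians for one condition and summarize.

    Excluded cells and cells without the requested readout contribute
    nothing. Warns when fewer than ``n_cells`` analyzable cells remain.
    """
    attr = f"median_{metric}_um"
    medians = [
        getattr(r, attr)
        for r in records
        if not r.excluded and not math.isnan(getattr(r, attr))
    ]
    if not medians:
        raise ValueError("zero analyzable cells")
    if len(medians) < n_cells:
        warnings.warn(
            f"only {len(medians)} analyzable cells (expected {n_cells})",
            stacklevel=2,
        )
    medians_arr = np.asarray(medians, dtype=float)
    pct = tuple(float(v) for v in np.percentile(medians_arr, [5, 25, 50, 75, 95]))
    return ConditionSummary(
        condition=condition,
        metric=metric,
        cell_medians_um=medians_arr,
        percentiles=pct,
        n_cells=len(medians),
    )


def csr_reference(green_density: float) -> CsrReference:
    """Analytic nearest-neighbor moments under complete spatial randomness.

    For a homogeneous Poisson process of intensity λ (points per μm²),
    the NN distance CDF is 1 - exp(-λπr²); the mean is 1/(2√λ) and the
    median √(ln 2 / (πλ)).
    """
    if not green_density > 0:
        raise ValueError("density must be positive")
    lam = float(green_density)
    return CsrReference(
        mean_nn_um=1.0 / (2.0 * math.sqrt(lam)),
        median_nn_um=math.sqrt(math.log(2.0) / (math.pi * lam)),
    )
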