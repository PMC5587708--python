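"""End-to-end orchestration of the synthetic → analysis pipeline.

One call takes a configuration (simulation model, render settings,
segmentation and proximity parameters), runs simulate → render →
segment → proximity → colocalization (optional) → statistics, and writes
CSV/JSON outputs plus a provenance manifest. All randomness flows from
the single top-level seed through per-stage derived seeds, so a rerun
with the same config is bit-identical for every deterministic stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import colocalization as coloc
from . import io as ppio
from . import proximity as prox
from . import segmentation as seg
from . import synthetic as syn
from . import stats as ppstats

__all__ = ["PipelineResult", "validate_config", "run_pipeline", "analyze_field"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_fields": 10,
    "model": {},        # CouplingModel overrides
    "render": {},       # RenderSpec overrides
    "channel_map": {"red": "red", "green": "green", "nuclei": "nuclei"},
    "segmentation": {"min_size_px": 4, "max_size_px": None},
    "proximity": {"k": 1.5, "filter_outliers": True, "n_cells": 50},
    "coloc": {"enabled": False, "roi_area_um2": 225.0},
}


@dataclass
class PipelineResult:
    out_dir: Path
    per_cell: pd.DataFrame
    summaries: dict
    coloc_table: pd.DataFrame | None
    manifest_path: Path


def _merged(config: dict) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        # channel_map is a complete role->label mapping, replaced atomically
        if k != "channel_map" and isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _coerce_offset_law(model_cfg: dict) -> dict:
    """Allow YAML/JSON configs to spell the offset law as a mapping."""
    law = model_cfg.get("offset_law")
    if isinstance(law, dict):
        if set(law) == {"fixed"}:
            model_cfg["offset_law"] = syn.FixedOffset(float(law["fixed"]))
        elif set(law) == {"rayleigh"}:
            model_cfg["offset_law"] = syn.RayleighOffset(float(law["rayleigh"]))
        else:
            raise ValueError(f"offset_law mapping must be fixed|rayleigh, got {law}")
    return model_cfg


def validate_config(config: dict) -> dict:
    """Merge with defaults and fail fast on inconsistencies."""
    cfg = _merged(config)
    cfg["model"] = _coerce_offset_law(cfg["model"])
    syn.CouplingModel(**{**cfg["model"], "seed": 0})  # raises on bad parameters
    syn.RenderSpec(**cfg["render"])
    required = {"red", "green", "nuclei"}
    missing = required - set(cfg["channel_map"])
    if missing:
        raise ValueError(f"channel_map missing roles: {sorted(missing)}")
    if cfg["n_fields"] < 1:
        raise ValueError("n_fields must be >= 1")
    return cfg


def _stage_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def analyze_field(
    field: syn.FieldImage,
    regions: list[seg.CellRegion],
    channel_map: dict[str, str],
    seg_cfg: dict,
    prox_cfg: dict,
    cell_id_offset: int = 0,
) -> tuple[list[seg.PunctaObject], list[prox.ProximityRecord]]:
    """Segment both puncta channels per cell and build proximity records."""
    red_img = field[channel_map["red"]]
    green_img = field[channel_map["green"]]
    objects: list[seg.PunctaObject] = []
    records: list[prox.ProximityRecord] = []
    for region in regions:
        red_obj = seg.segment_puncta(
            red_img, region,
            min_size_px=seg_cfg.get("min_size_px", 4),
            max_size_px=seg_cfg.get("max_size_px"),
        )
        green_obj = seg.segment_puncta(
            green_img, region,
            min_size_px=seg_cfg.get("min_size_px", 4),
            max_size_px=seg_cfg.get("max_size_px"),
        )
        uid = region.cell_id + cell_id_offset
        red_obj = [seg.PunctaObject(**{**o.__dict__, "cell_id": uid}) for o in red_obj]
        green_obj = [seg.PunctaObject(**{**o.__dict__, "cell_id": uid}) for o in green_obj]
        objects += red_obj + green_obj
        records.append(
            prox.cell_proximity(
                red_obj, green_obj, cell_id=uid,
                k=prox_cfg.get("k", 1.5),
                filter_outliers=prox_cfg.get("filter_outliers", True),
            )
        )
    return objects, records


def run_pipeline(config: dict, out_dir: str | Path) -> PipelineResult:
    """Run the full synthetic → analysis pipeline and write its outputs."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    field_seeds = _stage_seeds(seed, 3 * cfg["n_fields"])
    all_objects: list[seg.PunctaObject] = []
    all_records: list[prox.ProximityRecord] = []
    coloc_rows: list[dict] = []
    offset = 0
    render_spec = syn.RenderSpec(**cfg["render"])
    for i in range(cfg["n_fields"]):
        model = syn.CouplingModel(**{**cfg["model"], "seed": field_seeds[3 * i]})
        truth = syn.simulate_point_pattern(model)
        field = syn.render_field(truth, render_spec, seed=field_seeds[3 * i + 1])
        regions = syn.regions_from_truth(
            truth, render_spec.pixel_size_um,
            field[cfg["channel_map"]["red"]].shape,
        )
        ppio.write_field(field, out / f"field_{i:03d}.tif")
        ppio.write_ground_truth_csv(truth, out / f"field_{i:03d}_truth.csv", field_id=str(i))
        objects, records = analyze_field(
            field, regions, cfg["channel_map"], cfg["segmentation"],
            cfg["proximity"], cell_id_offset=offset,
        )
        all_objects += objects
        all_records += records
        if cfg["coloc"]["enabled"]:
            side = math.sqrt(cfg["coloc"]["roi_area_um2"])
            for region in regions:
                try:
                    roi = coloc.place_roi(
                        region, side, render_spec.pixel_size_um,
                        seed=field_seeds[3 * i + 2] + region.cell_id,
                    )
                except ValueError:
                    continue
                r = coloc.pearson(
                    field[cfg["channel_map"]["red"]],
                    field[cfg["channel_map"]["green"]], roi,
                )
                coloc_rows.append(
                    dict(field_id=i, cell_id=region.cell_id + offset,
                         pearson_r=r, roi_area_um2=roi.area_um2)
                )
        offset += len(regions)

    ppio.write_objects_csv(all_objects, out / "objects.csv")
    per_cell = pd.DataFrame(
        [
            dict(
                cell_id=r.cell_id,
                n_red=r.n_red,
                n_green=r.n_green,
                median_red_to_green_um=r.median_red_to_green_um,
                median_green_to_green_um=r.median_green_to_green_um,
                n_outliers_removed=r.n_outliers_removed,
                excluded_reason=r.excluded_reason,
            )
            for r in all_records
        ]
    )
    per_cell.to_csv(out / "proximity_per_cell.csv", index=False)
    summaries = {}
    for metric in ("red_to_green", "green_to_green"):
        try:
            s = prox.summarize_condition(
                all_records, n_cells=cfg["proximity"].get("n_cells", 50), metric=metric
            )
        except ValueError:
            continue
        summaries[metric] = dict(
            n_cells=s.n_cells,
            percentiles=dict(zip(("p5", "p25", "p50", "p75", "p95"), s.percentiles)),
        )
    if (
        "red_to_green" in summaries
        and "green_to_green" in summaries
        and summaries["red_to_green"]["n_cells"] >= 2
    ):
        rg = [r.median_red_to_green_um for r in all_records
              if not r.excluded and not math.isnan(r.median_red_to_green_um)]
        gg = [r.median_green_to_green_um for r in all_records
              if not r.excluded and not math.isnan(r.median_green_to_green_um)]
        t = ppstats.welch_t(rg, gg)
        summaries["welch_red_vs_green_spacing"] = dict(
            t=t.statistic, df=t.df, p_value=t.p_value
        )
    (out / "summary.json").write_text(json.dumps(summaries, indent=2))
    coloc_table = None
    if coloc_rows:
        coloc_table = pd.DataFrame(coloc_rows)
        coloc_table.to_csv(out / "coloc.csv", index=False)
    manifest = ppio.write_manifest(out, cfg, seed)
    return PipelineResult(out, per_cell, summaries, coloc_table, manifest)
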