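"""File formats and provenance manifests.

Fields travel as multi-page TIFF (one page per channel, or per frame for
time-lapse) with the pixel size recorded both in the TIFF resolution
tags and in a sidecar JSON; tables are CSV via pandas; every output
directory carries a manifest with the config hash, seed and library
versions. The pixel size must come from metadata or config — it is never
guessed, since every headline quantity is a physical distance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import ChannelImage, PunctaObject
from .synthetic import FieldImage, GroundTruth

__all__ = [
    "write_field",
    "read_field",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "objects_to_frame",
    "write_objects_csv",
    "read_objects_csv",
    "write_manifest",
    "config_hash",
]

_SIDECAR_SUFFIX = ".json"


def write_field(field: FieldImage, path: str | Path) -> Path:
    """Write a multi-channel field as multi-page TIFF + sidecar JSON."""
    path = Path(path)
    labels = list(field.channels)
    stack = np.stack([field.channels[c].intensities for c in labels]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata=None)
    sidecar = {
        "pixel_size_um": field.pixel_size_um,
        "channels": labels,
    }
    path.with_suffix(path.suffix + _SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=2))
    return path


def read_field(
    path: str | Path,
    pixel_size_um: float | None = None,
    channels: list[str] | None = None,
) -> FieldImage:
    """Read a multi-page TIFF back into a FieldImage.

    Pixel size and channel labels come from the sidecar JSON when
    present; otherwise they must be supplied. A missing pixel size is a
    hard error — physical units are never defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = path.with_suffix(path.suffix + _SIDECAR_SUFFIX)
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size_um = pixel_size_um or sidecar.get("pixel_size_um")
        channels = channels or sidecar.get("channels")
    if pixel_size_um is None:
        raise ValueError(
            f"{path}: pixel size not in sidecar metadata and not supplied"
        )
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if channels is None:
        channels = [f"ch{i}" for i in range(stack.shape[0])]
    if len(channels) != stack.shape[0]:
        raise ValueError(f"{path}: {stack.shape[0]} pages but {len(channels)} labels")
    chans = {
        label: ChannelImage(stack[i].astype(float), float(pixel_size_um), label)
        for i, label in enumerate(channels)
    }
    return FieldImage(chans, float(pixel_size_um))


def write_ground_truth_csv(truth: GroundTruth, path: str | Path, field_id: str = "0") -> Path:
    rows = []
    for cell in truth.cells:
        for ch in ("red", "green"):
            pts = getattr(cell, ch)
            for i, (x, y) in enumerate(pts):
                coupled = bool(cell.coupled[i]) if ch == "red" else False
                partner = int(cell.partner[i]) if ch == "red" else -1
                rows.append(
                    dict(
                        field_id=field_id,
                        cell_id=cell.cell_id,
                        channel=ch,
                        x_um=x,
                        y_um=y,
                        coupled_flag=coupled,
                        partner_index=partner,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "field_id", "cell_id", "channel", "x_um", "y_um", "coupled_flag", "partner_index",
        ],
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_ground_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def objects_to_frame(objects: list[PunctaObject], field_id: str = "0") -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                field_id=field_id,
                cell_id=o.cell_id,
                channel=o.channel_label,
                object_id=o.object_id,
                x_um=o.cm_x_um,
                y_um=o.cm_y_um,
                area_um2=o.area_um2,
                equivalent_radius_um=o.equivalent_radius_um,
                pixel_count=o.pixel_count,
            )
            for o in objects
        ],
        columns=[
            "field_id", "cell_id", "channel", "object_id", "x_um", "y_um",
            "area_um2", "equivalent_radius_um", "pixel_count",
        ],
    )


def write_objects_csv(objects: list[PunctaObject], path: str | Path, field_id: str = "0") -> Path:
    objects_to_frame(objects, field_id).to_csv(path, index=False)
    return Path(path)


def read_objects_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, seed: int) -> Path:
    import scipy

    from . import __version__

    manifest = {
        "punctaprox_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
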