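"""Disk formats: per-tile TIFFs with a plain-text manifest, mask/mosaic
TIFFs, CSV tables, and JSON provenance sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imgproc import BinaryFrame, Mosaic
from .morphometry import FrameMetrics
from .simulate import TileSet

MANIFEST_COLUMNS = ["tile", "row", "col", "offset_y_px", "offset_x_px", "time_h"]


def write_tileset(tileset: TileSet, directory: str | Path, prefix: str = "tile") -> Path:
    """Write one frame's tiles as TIFFs plus a ``manifest.csv`` naming the
    nominal grid offsets; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows, cols = tileset.grid
    records = []
    for k, (tile, (oy, ox)) in enumerate(zip(tileset.tiles, tileset.nominal_offsets)):
        r, c = divmod(k, cols)
        name = f"{prefix}_r{r}_c{c}.tif"
        tifffile.imwrite(directory / name, tile)
        records.append(
            {
                "tile": name, "row": r, "col": c,
                "offset_y_px": int(oy), "offset_x_px": int(ox),
                "time_h": tileset.time_h,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS).to_csv(
        manifest, index=False
    )
    meta = {
        "grid_rows": rows, "grid_cols": cols,
        "px_size_um": tileset.px_size_um, "time_h": tileset.time_h,
    }
    (directory / "tileset.json").write_text(json.dumps(meta, indent=2))
    return manifest


def read_tileset(directory: str | Path) -> TileSet:
    """Read a tile directory written by :func:`write_tileset` (or by a
    user following the same manifest convention)."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"missing manifest: {manifest}")
    df = pd.read_csv(manifest)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {manifest} lacks columns {sorted(missing)}")
    meta_path = directory / "tileset.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        grid = (int(meta["grid_rows"]), int(meta["grid_cols"]))
        px = float(meta.get("px_size_um", 1.3))
    else:
        grid = (int(df["row"].max()) + 1, int(df["col"].max()) + 1)
        px = 1.3
    df = df.sort_values(["row", "col"]).reset_index(drop=True)
    tiles = [tifffile.imread(directory / name) for name in df["tile"]]
    offsets = df[["offset_y_px", "offset_x_px"]].to_numpy(dtype=int)
    return TileSet(
        tiles=tiles, nominal_offsets=offsets, grid=grid,
        time_h=float(df["time_h"].iloc[0]), px_size_um=px,
    )


def write_mosaic(mosaic: Mosaic, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mosaic.image)
    _write_provenance(path, mosaic.provenance,
                      time_h=mosaic.time_h, px_size_um=mosaic.px_size_um)


def write_mask(frame: BinaryFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, frame.mask.astype(np.uint8) * 255)
    _write_provenance(
        path, frame.provenance, time_h=frame.time_h,
        px_size_um=frame.px_size_um,
        threshold_method=frame.threshold_method,
        threshold_value=frame.threshold_value,
    )


def _write_provenance(img_path: Path, provenance: list, **extra) -> None:
    sidecar = img_path.with_suffix(img_path.suffix + ".json")
    payload = {"provenance": provenance, **extra}
    sidecar.write_text(json.dumps(payload, indent=2, default=str))


def write_metrics_csv(metrics: list[FrameMetrics], path: str | Path) -> None:
    """FrameMetrics series as CSV; header names carry units."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "time_h": [m.time_h for m in metrics],
            "n_objects": [m.n_objects for m in metrics],
            "occupied_area_um2": [m.occupied_area_um2 for m in metrics],
            "colony_diameter_um": [m.colony_diameter_um for m in metrics],
            "germinated_count": [m.germinated_count for m in metrics],
        }
    )
    df.to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_h", "n_objects", "occupied_area_um2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metrics file {path} lacks columns {sorted(missing)}")
    return df
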