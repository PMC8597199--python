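"""Object-level and frame-level measurements on binary masks.

Objects are 8-connected components (visual connection in a 2D mosaic);
labels follow deterministic raster-scan order.  Areas are pixel counts
converted by the square of the pixel pitch.  Germination is scored
morphologically: an object counts as germinated once it is clearly larger
than a resting spore or clearly elongated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as skmeasure

from .imgproc import BinaryFrame

__all__ = [
    "FrameMetrics",
    "label_objects",
    "measure_objects",
    "occupied_area",
    "colony_diameter",
    "classify_germinated",
    "frame_metrics",
]


@dataclass
class FrameMetrics:
    """Per-frame summary for one culture replicate."""

    time_h: float
    n_objects: int
    occupied_area_um2: float
    colony_diameter_um: float | None
    germinated_count: int | None


def _mask_of(mask_or_frame) -> tuple[np.ndarray, float]:
    if isinstance(mask_or_frame, BinaryFrame):
        return mask_or_frame.mask, mask_or_frame.px_size_um
    return np.asarray(mask_or_frame, dtype=bool), 1.0


def label_objects(mask) -> np.ndarray:
    """Label 8-connected foreground components 1..K (0 = background)."""
    m, _ = _mask_of(mask)
    return skmeasure.label(m, connectivity=2)


def measure_objects(
    labels: np.ndarray, px_size_um: float = 1.3, min_area_um2: float = 0.0
) -> pd.DataFrame:
    """One row per labelled object.

    Columns: label, area_px, area_um2, centroid x/y (um, x = column
    direction), bbox (min_row, min_col, max_row, max_col), major/minor
    axis lengths (um) and eccentricity.  Empty labelling gives an empty
    table with the same columns.

    ``min_area_um2`` drops objects below a particle-size floor (the
    standard guard against residual noise specks when counting spores;
    0 keeps everything).
    """
    cols = [
        "label", "area_px", "area_um2", "centroid_x_um", "centroid_y_um",
        "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
        "major_axis_um", "minor_axis_um", "eccentricity",
    ]
    if labels.max() == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    props = skmeasure.regionprops_table(
        labels,
        properties=(
            "label", "area", "centroid", "bbox",
            "axis_major_length", "axis_minor_length", "eccentricity",
        ),
    )
    area_px = props["area"].astype(np.int64)
    table = pd.DataFrame(
        {
            "label": props["label"].astype(np.int64),
            "area_px": area_px,
            "area_um2": area_px * px_size_um**2,
            "centroid_x_um": props["centroid-1"] * px_size_um,
            "centroid_y_um": props["centroid-0"] * px_size_um,
            "bbox_min_row": props["bbox-0"],
            "bbox_min_col": props["bbox-1"],
            "bbox_max_row": props["bbox-2"],
            "bbox_max_col": props["bbox-3"],
            "major_axis_um": props["axis_major_length"] * px_size_um,
            "minor_axis_um": props["axis_minor_length"] * px_size_um,
            # degenerate (collinear) objects come back with ecc == 1.0;
            # keep the documented [0, 1) range
            "eccentricity": np.clip(
                props["eccentricity"], 0.0, np.nextafter(1.0, 0.0)
            ),
        }
    )
    if min_area_um2 > 0:
        table = table[table["area_um2"] >= min_area_um2].reset_index(drop=True)
    return table


def occupied_area(table: pd.DataFrame) -> float:
    """Total occupied area in um^2 (sum of object areas = foreground
    pixel count times the pixel area)."""
    if len(table) == 0:
        return 0.0
    return float(table["area_um2"].sum())


def _max_pairwise_distance(pts: np.ndarray) -> float:
    """Exact maximum pairwise Euclidean distance between points."""
    if len(pts) == 1:
        return 0.0
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: brute force on the originals
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return math.sqrt(float(d2.max()))


def colony_diameter(mask, px_size_um: float | None = None, method: str = "feret") -> float:
    """Diameter of the largest object, in micrometres.

    ``method="feret"`` (default): maximum pairwise distance between the
    foreground pixel centres of the largest 8-connected object.
    ``method="equivalent"``: diameter of the circle with the same area.
    Raises on an empty mask.
    """
    m, px = _mask_of(mask)
    if px_size_um is not None:
        px = px_size_um
    if not m.any():
        raise ValueError("empty mask: colony diameter undefined")
    labels = label_objects(m)
    largest = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    if method == "equivalent":
        area = float(np.count_nonzero(labels == largest)) * px * px
        return 2.0 * math.sqrt(area / math.pi)
    if method != "feret":
        raise ValueError(f"unknown diameter method {method!r}")
    rr, cc = np.nonzero(labels == largest)
    pts = np.column_stack([rr, cc]).astype(np.float64)
    return _max_pairwise_distance(pts) * px


def classify_germinated(
    table: pd.DataFrame,
    baseline_spore_area_um2: float,
    area_factor: float = 2.0,
    ecc_min: float = 0.85,
) -> tuple[pd.DataFrame, int]:
    """Flag objects as germinated and return (table, germinated count).

    An object is scored germinated when its area reaches ``area_factor``
    times the resting-spore baseline (typically the median object area of
    the time-0 frame) or when it is strongly elongated
    (eccentricity >= ``ecc_min``) — a germ tube stretches the object long
    before it doubles its area.
    """
    if baseline_spore_area_um2 is None or not baseline_spore_area_um2 > 0:
        raise ValueError("baseline spore area is required and must be positive")
    table = table.copy()
    if len(table) == 0:
        table["germinated"] = pd.Series(dtype=bool)
        return table, 0
    flags = (table["area_um2"] >= area_factor * baseline_spore_area_um2) | (
        table["eccentricity"] >= ecc_min
    )
    table["germinated"] = flags
    return table, int(flags.sum())


def frame_metrics(
    frame: BinaryFrame,
    baseline_spore_area_um2: float | None = None,
    with_diameter: bool = False,
    diameter_method: str = "feret",
    min_area_um2: float = 0.0,
    area_factor: float = 2.0,
    ecc_min: float = 0.85,
) -> tuple[FrameMetrics, pd.DataFrame]:
    """Measure one binary frame: label, per-object table, and the frame
    summary.  Diameter is computed only on request and only when the
    mask is non-empty."""
    labels = label_objects(frame.mask)
    table = measure_objects(labels, frame.px_size_um, min_area_um2=min_area_um2)
    germinated = None
    if baseline_spore_area_um2 is not None:
        table, germinated = classify_germinated(
            table, baseline_spore_area_um2, area_factor, ecc_min
        )
    diameter = None
    if with_diameter and frame.mask.any():
        diameter = colony_diameter(
            frame.mask, frame.px_size_um, method=diameter_method
        )
    metrics = FrameMetrics(
        time_h=frame.time_h,
        n_objects=int(len(table)),
        occupied_area_um2=occupied_area(table),
        colony_diameter_um=diameter,
        germinated_count=germinated,
    )
    return metrics, table
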