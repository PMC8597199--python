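"""Mosaic reconstruction and binarisation.

Implements the processing chain applied to each time point of the
micrograph series: tiles are stitched into one mosaic (nominal grid
placement, optionally refined by phase correlation over the overlaps),
then the mosaic is denoised (median filter), contrast-enhanced (CLAHE),
background-corrected (rolling ball), smoothed (mean then maximum filter)
and finally converted to a binary mask by automatic histogram
thresholding — Yen's criterion for the spore-only frame at time 0, Otsu's
criterion for all later frames.

All images are 8-bit grayscale; thresholds are selected over the fixed
0..255 histogram with ties broken toward the lowest qualifying value, and
foreground is ``image > threshold``.  Every step appends its name and
parameters to the mosaic's provenance list.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import exposure, restoration, transform
from skimage.registration import phase_cross_correlation

from .simulate import TileSet

__all__ = [
    "Mosaic",
    "BinaryFrame",
    "ProcessParams",
    "adaptive_ball_radius",
    "stitch_tiles",
    "median_filter",
    "enhance_local_contrast",
    "subtract_background",
    "smooth_clean",
    "otsu_threshold",
    "yen_threshold",
    "binarize",
    "process_mosaic",
]


@dataclass
class Mosaic:
    """One stitched grayscale frame with its processing history."""

    image: np.ndarray
    time_h: float
    px_size_um: float
    provenance: list = field(default_factory=list)

    def with_image(self, image: np.ndarray, step: str, **params) -> "Mosaic":
        prov = list(self.provenance) + [{"step": step, **params}]
        return Mosaic(
            image=image, time_h=self.time_h, px_size_um=self.px_size_um,
            provenance=prov,
        )


@dataclass
class BinaryFrame:
    """Thresholded mask for one frame."""

    mask: np.ndarray
    time_h: float
    px_size_um: float
    threshold_method: str
    threshold_value: float | None
    provenance: list = field(default_factory=list)


def _as_uint8(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img
    return np.clip(np.rint(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# stitching


def _pairwise_shift(
    ref: np.ndarray, mov: np.ndarray, max_shift_px: int
) -> tuple[int, int] | None:
    """Integer shift of ``mov``'s source position relative to ``ref``'s
    over matched overlap windows, or None when the correlation peak is
    unconvincing (featureless overlap, out-of-window shift, or poor
    agreement after alignment)."""
    if min(ref.shape) < 4 or min(mov.shape) < 4:
        return None
    ref = ref.astype(np.float64)
    mov = mov.astype(np.float64)
    if float(ref.std()) < 1e-6 or float(mov.std()) < 1e-6:
        return None
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=1)
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    if abs(dy) > max_shift_px or abs(dx) > max_shift_px:
        return None
    # validate: Pearson correlation of the aligned, non-wrapped parts
    h, w = ref.shape
    ry0, my0 = max(dy, 0), max(-dy, 0)
    rx0, mx0 = max(dx, 0), max(-dx, 0)
    hh, ww = h - abs(dy), w - abs(dx)
    if hh < 2 or ww < 2:
        return None
    a = ref[ry0 : ry0 + hh, rx0 : rx0 + ww].ravel()
    b = mov[my0 : my0 + hh, mx0 : mx0 + ww].ravel()
    if a.std() < 1e-9 or b.std() < 1e-9:
        return None
    corr = float(np.corrcoef(a, b)[0, 1])
    if not np.isfinite(corr) or corr < 0.5:
        return None
    return dy, dx


def stitch_tiles(
    tileset: TileSet,
    refine: bool = False,
    max_shift_px: int = 5,
    blend: str = "feather",
) -> Mosaic:
    """Reassemble tiles into one mosaic.

    With ``refine`` each tile's placement is corrected relative to its
    already-placed left (or, for the first column, top) neighbour by the
    phase-correlation peak over the nominal overlap window, searched
    within ``+-max_shift_px``; an unconvincing peak falls back to the
    nominal offset with a warning.  Overlaps are combined by feathered
    averaging (``blend="feather"``) or by straight overwrite in placement
    order (``blend="none"``, exact outside nothing — every pixel comes
    from exactly one tile).
    """
    if not tileset.tiles:
        raise ValueError("empty tileset")
    if blend not in ("feather", "none"):
        raise ValueError(f"unknown blend mode {blend!r}")
    rows, cols = tileset.grid
    if rows * cols != len(tileset.tiles):
        raise ValueError("tile count does not match grid")

    nominal = np.asarray(tileset.nominal_offsets, dtype=int)
    offsets = nominal.copy()

    if refine and len(tileset.tiles) > 1:
        for r in range(rows):
            for c in range(cols):
                k = r * cols + c
                if r == 0 and c == 0:
                    continue
                if c > 0:
                    j = r * cols + (c - 1)
                else:
                    j = (r - 1) * cols + c
                ref_tile, mov_tile = tileset.tiles[j], tileset.tiles[k]
                th, tw = mov_tile.shape
                # nominal overlap window in frame coordinates
                y0 = max(nominal[k, 0], nominal[j, 0])
                x0 = max(nominal[k, 1], nominal[j, 1])
                y1 = min(nominal[k, 0] + th, nominal[j, 0] + ref_tile.shape[0])
                x1 = min(nominal[k, 1] + tw, nominal[j, 1] + ref_tile.shape[1])
                pad = max_shift_px
                ry0, rx0 = y0 - nominal[j, 0], x0 - nominal[j, 1]
                my0, mx0 = y0 - nominal[k, 0], x0 - nominal[k, 1]
                hh, ww = y1 - y0, x1 - x0
                ref_win = ref_tile[ry0 : ry0 + hh, rx0 : rx0 + ww]
                mov_win = mov_tile[my0 : my0 + hh, mx0 : mx0 + ww]
                found = _pairwise_shift(ref_win, mov_win, max_shift_px)
                if found is None:
                    warnings.warn(
                        f"stitch refinement: no confident correlation peak for "
                        f"tile ({r},{c}); keeping nominal offset",
                        stacklevel=2,
                    )
                    rel = offsets[j] - nominal[j]
                else:
                    rel = offsets[j] - nominal[j] + np.array(found)
                offsets[k] = nominal[k] + rel

    offsets = offsets - offsets.min(axis=0)
    h = int(max(o[0] + t.shape[0] for o, t in zip(offsets, tileset.tiles)))
    w = int(max(o[1] + t.shape[1] for o, t in zip(offsets, tileset.tiles)))

    if blend == "none":
        canvas = np.zeros((h, w), dtype=np.uint8)
        for off, tile in zip(offsets, tileset.tiles):
            canvas[off[0] : off[0] + tile.shape[0], off[1] : off[1] + tile.shape[1]] = tile
        out = canvas
    else:
        acc = np.zeros((h, w), dtype=np.float64)
        wts = np.zeros((h, w), dtype=np.float64)
        for off, tile in zip(offsets, tileset.tiles):
            th, tw = tile.shape
            fy = np.minimum(np.arange(th) + 1, np.arange(th)[::-1] + 1)
            fx = np.minimum(np.arange(tw) + 1, np.arange(tw)[::-1] + 1)
            wt = np.minimum.outer(fy, fx).astype(np.float64)
            acc[off[0] : off[0] + th, off[1] : off[1] + tw] += wt * tile
            wts[off[0] : off[0] + th, off[1] : off[1] + tw] += wt
        out = _as_uint8(acc / np.maximum(wts, 1e-12))

    return Mosaic(
        image=out,
        time_h=tileset.time_h,
        px_size_um=tileset.px_size_um,
        provenance=[
            {
                "step": "stitch",
                "refine": refine,
                "max_shift_px": max_shift_px,
                "blend": blend,
                "grid": list(tileset.grid),
                "offsets_px": offsets.tolist(),
            }
        ],
    )


# ---------------------------------------------------------------------------
# intensity filters


def median_filter(img: np.ndarray, radius_px: int = 2) -> np.ndarray:
    """Median over the (2r+1)^2 neighbourhood, reflecting at the edges."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    return ndimage.median_filter(_as_uint8(img), size=2 * radius_px + 1, mode="reflect")


def enhance_local_contrast(
    img: np.ndarray, kernel_frac: float = 1 / 8, clip_limit: float = 2.0
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation (CLAHE).

    ``kernel_frac`` sets the contextual-region size as a fraction of each
    image dimension; ``clip_limit`` is the histogram slope limit (ImageJ
    convention — the per-bin count is clipped at ``clip_limit`` times the
    uniform level, excess redistributed).  ``kernel_frac=1`` with an
    unlimited clip is global histogram equalisation and is computed as
    such in closed form.
    """
    if not (0 < kernel_frac <= 1):
        raise ValueError("kernel_frac must lie in (0, 1]")
    img = _as_uint8(img)
    if img.std() == 0:
        return img.copy()
    if kernel_frac >= 1.0 and not np.isfinite(clip_limit):
        # limiting case: one contextual region, no clipping
        return _as_uint8(255.0 * exposure.equalize_hist(img, nbins=256))
    kernel = tuple(max(8, int(round(s * kernel_frac))) for s in img.shape)
    out = exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=min(clip_limit / 256.0, 1.0), nbins=256
    )
    return _as_uint8(255.0 * out)


def subtract_background(img: np.ndarray, ball_radius_px: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is a morphological rolling-ball estimate; for large
    radii it is computed on a shrunken copy of the image (shrink factor
    ~radius/10, mirroring the classic implementation) and resized back,
    which is indistinguishable for structures much smaller than the ball.
    The corrected image is clipped at 0.
    """
    if ball_radius_px < 1:
        raise ValueError("ball_radius_px must be >= 1")
    img = _as_uint8(img)
    shrink = max(1, ball_radius_px // 10)
    if shrink > 1 and min(img.shape) // shrink >= 8:
        small = transform.rescale(
            img.astype(np.float64), 1.0 / shrink, order=1, anti_aliasing=True,
            preserve_range=True,
        )
        bg_small = restoration.rolling_ball(small, radius=ball_radius_px / shrink)
        bg = transform.resize(
            bg_small, img.shape, order=1, preserve_range=True, anti_aliasing=False
        )
    else:
        bg = restoration.rolling_ball(img, radius=ball_radius_px)
    out = img.astype(np.float64) - bg
    return _as_uint8(np.clip(out, 0, 255))


def adaptive_ball_radius(img: np.ndarray, base_radius_px: int = 50) -> int:
    """Rolling-ball radius large enough for the structures in ``img``.

    The ball must exceed the largest foreground object's half-width or
    the background estimate rises inside large bright plateaus and
    carves them apart.  A quick Otsu pre-segmentation of the image
    bounds the largest object's bbox half-width; the returned radius is
    that half-width plus a margin, never below ``base_radius_px``.
    """
    img = _as_uint8(img)
    try:
        thr = otsu_threshold(img)
    except ValueError:
        return base_radius_px
    pre = img > thr
    if not pre.any() or pre.mean() > 0.5:
        # empty or inverted-looking pre-segmentation: stay with the base
        return base_radius_px
    lbl, k = ndimage.label(pre, structure=ndimage.generate_binary_structure(2, 2))
    if k == 0:
        return base_radius_px
    largest = int(np.argmax(ndimage.sum_labels(pre, lbl, np.arange(1, k + 1)))) + 1
    sl = ndimage.find_objects((lbl == largest).astype(np.int32))[0]
    half_width = max(sl[0].stop - sl[0].start, sl[1].stop - sl[1].start) // 2
    return max(base_radius_px, half_width + 25)


def smooth_clean(
    img: np.ndarray, mean_radius_px: int = 1, max_radius_px: int = 1
) -> np.ndarray:
    """Mean filter followed by maximum filter (gap closing), in that order."""
    if mean_radius_px < 1 or max_radius_px < 1:
        raise ValueError("filter radii must be >= 1")
    img = _as_uint8(img)
    out = ndimage.uniform_filter(
        img.astype(np.float64), size=2 * mean_radius_px + 1, mode="reflect"
    )
    out = ndimage.maximum_filter(out, size=2 * max_radius_px + 1, mode="reflect")
    return _as_uint8(out)


# ---------------------------------------------------------------------------
# thresholding


def _histogram256(img: np.ndarray) -> np.ndarray:
    img = _as_uint8(img)
    return np.bincount(img.ravel(), minlength=256).astype(np.float64)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold on the 0..255 histogram.

    Maximises the between-class variance w0*w1*(mu0-mu1)^2 over all 255
    splits ``t`` (classes ``<= t`` and ``> t``); ties resolve to the
    lowest qualifying threshold.  Raises on a constant image.
    """
    hist = _histogram256(img)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has a single intensity")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * levels)[:-1]
    total_mean = float(np.sum(p * levels))
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(255)
    sigma_b[valid] = (total_mean * w0[valid] - cum_mean[valid]) ** 2 / (
        w0[valid] * w1[valid]
    )
    return int(np.argmax(sigma_b))


def yen_threshold(img: np.ndarray) -> int:
    """Yen's maximum-correlation threshold on the 0..255 histogram.

    Maximises TC(t) = -ln[ G0(t) * G1(t) / (P0(t)^2 * P1(t)^2) ] where
    G are the within-class sums of squared probabilities and P the class
    probabilities; ties resolve to the lowest qualifying threshold.
    """
    hist = _histogram256(img)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has a single intensity")
    p = hist / hist.sum()
    P0 = np.cumsum(p)[:-1]
    P1 = 1.0 - P0
    G0 = np.cumsum(p * p)[:-1]
    G1 = float(np.sum(p * p)) - G0
    valid = (P0 > 0) & (P1 > 0) & (G0 > 0) & (G1 > 0)
    crit = np.full(255, -np.inf)
    crit[valid] = -np.log(G0[valid] * G1[valid]) + 2.0 * np.log(
        P0[valid] * P1[valid]
    )
    return int(np.argmax(crit))


def binarize(mosaic: Mosaic, method: str | None = None) -> BinaryFrame:
    """Threshold a mosaic into a BinaryFrame.

    ``method`` is "yen" or "otsu"; by default Yen is used for the frame
    at time 0 (spores only) and Otsu afterwards.  A constant (all
    background) mosaic yields an empty mask with a warning instead of an
    error.
    """
    if method is None:
        method = "yen" if mosaic.time_h == 0 else "otsu"
    if method not in ("yen", "otsu"):
        raise ValueError(f"unknown threshold method {method!r}")
    img = _as_uint8(mosaic.image)
    try:
        thr = yen_threshold(img) if method == "yen" else otsu_threshold(img)
        mask = img > thr
    except ValueError:
        warnings.warn(
            "degenerate histogram (constant mosaic); returning empty mask",
            stacklevel=2,
        )
        thr = None
        mask = np.zeros_like(img, dtype=bool)
    prov = list(mosaic.provenance) + [
        {"step": "binarize", "method": method, "threshold": thr}
    ]
    return BinaryFrame(
        mask=mask,
        time_h=mosaic.time_h,
        px_size_um=mosaic.px_size_um,
        threshold_method=method,
        threshold_value=thr,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# full chain


@dataclass(frozen=True)
class ProcessParams:
    """Parameters of the mosaic-to-mask chain.

    The declared order is median -> CLAHE -> background subtraction ->
    mean/max smoothing -> binarisation.  Setting a step's parameter to
    ``None`` disables that step (the defaults run everything, which is
    appropriate for noisy micrographs; noise-free synthetic input can be
    thresholded directly).
    """

    median_radius_px: int | None = 2
    clahe_kernel_frac: float | None = 1 / 8
    clahe_clip_limit: float = 2.0
    ball_radius_px: int | None = 50
    # enlarge the ball beyond the largest detected object's half-width
    # (late frames hold a single colony far wider than any fixed default)
    adapt_ball_radius: bool = True
    mean_radius_px: int | None = 1
    max_radius_px: int | None = 1
    threshold_method: str | None = None  # None = yen at t=0, otsu later

    @classmethod
    def direct(cls) -> "ProcessParams":
        """Threshold-only chain for clean (noise- and gradient-free) input."""
        return cls(
            median_radius_px=None, clahe_kernel_frac=None, ball_radius_px=None,
            mean_radius_px=None, max_radius_px=None,
        )


def process_mosaic(mosaic: Mosaic, params: ProcessParams = ProcessParams()) -> BinaryFrame:
    """Run the processing chain on a stitched mosaic and return its mask."""
    m = mosaic
    if params.median_radius_px is not None:
        m = m.with_image(
            median_filter(m.image, params.median_radius_px),
            "median", radius_px=params.median_radius_px,
        )
    if params.clahe_kernel_frac is not None:
        m = m.with_image(
            enhance_local_contrast(
                m.image, params.clahe_kernel_frac, params.clahe_clip_limit
            ),
            "clahe", kernel_frac=params.clahe_kernel_frac,
            clip_limit=params.clahe_clip_limit,
        )
    if params.ball_radius_px is not None:
        radius = params.ball_radius_px
        if params.adapt_ball_radius:
            radius = adaptive_ball_radius(m.image, radius)
        m = m.with_image(
            subtract_background(m.image, radius),
            "subtract_background", ball_radius_px=radius,
            adapted=params.adapt_ball_radius,
        )
    if params.mean_radius_px is not None or params.max_radius_px is not None:
        mr = params.mean_radius_px or 1
        xr = params.max_radius_px or 1
        m = m.with_image(
            smooth_clean(m.image, mr, xr),
            "smooth_clean", mean_radius_px=mr, max_radius_px=xr,
        )
    return binarize(m, params.threshold_method)
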