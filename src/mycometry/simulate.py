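"""Synthetic time-lapse generator for a germinating spore field.

Emulates the imaging experiment the analysis modules expect: a droplet of
spores deposited on a membrane, heterogeneous germination lags, germ-tube
emission, tip extension with angular diffusion, stochastic branching, and
the resulting coalescence of visually distinct objects into a single
colony.  Frames are rendered on a pixel grid, degraded with an illumination
gradient and sensor noise, and cut into overlapping tiles, so the full
processing chain (stitching, filtering, thresholding, morphometry) can be
exercised against known ground truth.

Geometry is tracked in micrometres in a continuous plane; rasterisation
uses 0-based pixel indices with the origin at the top-left and pixel
centres at integer coordinates.  Areas are pixel counts times the square
of the pixel pitch (default 1.3 um, i.e. 1.69 um^2 per pixel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import measure as skmeasure

__all__ = [
    "SimConfig",
    "ColonyState",
    "TileSet",
    "FrameTruth",
    "GroundTruth",
    "scaled_study_config",
    "init_spore_field",
    "advance_colony",
    "rasterize_frame",
    "render_tiles",
    "generate_series",
]

#: Observation schedule of the emulated experiment (hours).
DEFAULT_FRAME_TIMES_H = (0.0, 23.0, 26.0, 29.0, 46.5, 49.5, 52.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated culture replicate.

    Defaults describe the emulated study conditions: roughly 650-715
    spores of mean area 560 um^2 inside a ~7 mm droplet mark, a 12288 px
    square field at 1.3 um/px, 5x5 tiles with 10 % overlap, and frames at
    0, 23, 26, 29, 46.5, 49.5 and 52 h.  Kinetic parameters (tip speed,
    branch rate, lag distribution) are calibration choices: the lag
    distribution is moment-matched to a fast-germinating culture
    (78/90/94 % cumulative germination at 23/26/29 h) and tip kinetics are
    set so that coalescence into a single object completes between 29 h
    and 46.5 h.
    """

    n_spores: int = 687
    droplet_radius_um: float = 3500.0
    spore_area_mean_um2: float = 560.0
    spore_area_cv: float = 0.25
    lag_mean_h: float = 19.7
    lag_sd_h: float = 4.8
    tip_speed_um_h: float = 16.0
    branch_rate_per_tip_h: float = 0.18
    tip_angle_sd_rad: float = 0.35  # heading diffusion per sqrt(hour)
    hypha_width_um: float = 3.9
    frame_times_h: tuple[float, ...] = DEFAULT_FRAME_TIMES_H
    px_size_um: float = 1.3
    field_size_px: int = 12288
    tile_grid: tuple[int, int] = (5, 5)
    overlap_frac: float = 0.10
    illum_gradient_amp: float = 0.15
    noise_sd: float = 6.0
    foreground_level: int = 180
    background_level: int = 60
    min_gap_um: float = 13.0
    max_active_tips: int = 30000
    dt_h: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spores <= 0:
            raise ValueError("n_spores must be positive")
        times = tuple(float(t) for t in self.frame_times_h)
        if len(times) == 0 or times[0] != 0.0:
            raise ValueError("frame_times_h must start at 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame_times_h must be strictly increasing")
        if not (0.0 <= self.overlap_frac < 0.5):
            raise ValueError("overlap_frac must lie in [0, 0.5)")
        if self.px_size_um <= 0:
            raise ValueError("px_size_um must be positive")
        for name in ("tip_speed_um_h", "branch_rate_per_tip_h",
                     "tip_angle_sd_rad", "noise_sd", "illum_gradient_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.spore_area_mean_um2 <= 0 or self.spore_area_cv < 0:
            raise ValueError("invalid spore area distribution parameters")
        if self.lag_mean_h <= 0 or self.lag_sd_h < 0:
            raise ValueError("invalid lag distribution parameters")
        if min(self.tile_grid) < 1:
            raise ValueError("tile_grid must be at least 1x1")
        if self.field_size_px < 8:
            raise ValueError("field_size_px too small")

    @property
    def field_size_um(self) -> float:
        return self.field_size_px * self.px_size_um

    @property
    def field_center_um(self) -> tuple[float, float]:
        c = 0.5 * self.field_size_um
        return (c, c)


def scaled_study_config(scale: float, seed: int = 0, **overrides) -> SimConfig:
    """A density-preserving shrink of the study-scale default configuration.

    Linear dimensions (droplet radius, field size) scale by ``scale`` and
    the spore count by ``scale**2``, so nearest-neighbour spacing — the
    quantity that controls coalescence timing — is preserved.  Useful for
    desk-scale runs of the full pipeline.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must lie in (0, 1]")
    base = SimConfig()
    params = dict(
        n_spores=max(1, round(base.n_spores * scale * scale)),
        droplet_radius_um=base.droplet_radius_um * scale,
        field_size_px=max(64, round(base.field_size_px * scale)),
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class ColonyState:
    """Evolving geometry of one simulated spore field.

    Segments are straight hyphal pieces (x0, y0, x1, y1) in micrometres;
    every segment carries the index of the spore whose germ tube founded
    its lineage.  Tips are growth fronts (position, heading).
    """

    time_h: float
    centers_um: np.ndarray          # (n, 2) spore centres, um
    radii_um: np.ndarray            # (n,) spore disc radii, um
    lag_h: np.ndarray               # (n,) germination lag times, h
    germinated: np.ndarray          # (n,) bool, germ tube already emitted
    seg_coords: list                # list of (x0, y0, x1, y1) um
    seg_spore: list                 # founding spore index per segment
    tip_pos: np.ndarray             # (m, 2) um
    tip_heading: np.ndarray         # (m,) radians
    tip_spore: np.ndarray           # (m,) founding spore index
    rng: np.random.Generator

    @property
    def n_segments(self) -> int:
        return len(self.seg_coords)

    @property
    def n_active_tips(self) -> int:
        return len(self.tip_pos)

    def copy(self) -> "ColonyState":
        return ColonyState(
            time_h=self.time_h,
            centers_um=self.centers_um.copy(),
            radii_um=self.radii_um.copy(),
            lag_h=self.lag_h.copy(),
            germinated=self.germinated.copy(),
            seg_coords=list(self.seg_coords),
            seg_spore=list(self.seg_spore),
            tip_pos=self.tip_pos.copy(),
            tip_heading=self.tip_heading.copy(),
            tip_spore=self.tip_spore.copy(),
            rng=self.rng,
        )


@dataclass
class TileSet:
    """Raw tiles of one frame with their nominal grid offsets (row, col -> y, x px)."""

    tiles: list                      # list of 2D uint8 arrays, row-major
    nominal_offsets: np.ndarray      # (k, 2) int, (y, x) placement in px
    grid: tuple[int, int]
    time_h: float
    px_size_um: float
    true_offsets: np.ndarray | None = None  # actual cut positions when jittered


@dataclass
class FrameTruth:
    """Ground truth for one rendered frame."""

    time_h: float
    mask: np.ndarray                 # bool, true foreground
    n_objects: int                   # 8-connected components of the mask
    occupied_px: int
    germinated_count: int


@dataclass
class GroundTruth:
    """Per-replicate ground truth: spore table plus per-frame truths."""

    centers_um: np.ndarray
    areas_um2: np.ndarray
    lag_h: np.ndarray
    frames: list                     # list[FrameTruth]

    def spore_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "spore_id": np.arange(len(self.lag_h)),
                "x_um": self.centers_um[:, 0],
                "y_um": self.centers_um[:, 1],
                "area_um2": self.areas_um2,
                "lag_h": self.lag_h,
            }
        )


# ---------------------------------------------------------------------------
# spore field initialisation


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) of a lognormal with the given mean and sd."""
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def init_spore_field(config: SimConfig) -> ColonyState:
    """Deposit the spore field inside the droplet mark.

    Centres are uniform in the droplet disc subject to a minimum
    centre-to-edge gap (spores settle as distinct objects; the emulated
    counts at time zero are counts of separable particles).  Spore areas
    and germination lags are lognormal with the configured moments.
    Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If the droplet is too crowded to place ``n_spores`` non-touching
        spores (the packing constraint is named in the message).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_spores

    mu_a, sd_a = _lognormal_params(
        config.spore_area_mean_um2,
        config.spore_area_cv * config.spore_area_mean_um2,
    )
    areas = rng.lognormal(mu_a, sd_a, size=n)
    radii = np.sqrt(areas / math.pi)

    mu_l, sd_l = _lognormal_params(config.lag_mean_h, config.lag_sd_h)
    lags = rng.lognormal(mu_l, sd_l, size=n)

    cx, cy = config.field_center_um
    r_drop = config.droplet_radius_um
    # feasibility: total disc area (with gap margin) vs droplet area
    eff_r = radii + 0.5 * config.min_gap_um
    if np.sum(math.pi * eff_r**2) > 0.7 * math.pi * r_drop**2:
        raise ValueError(
            "droplet too small: cannot place "
            f"{n} spores with min_gap_um={config.min_gap_um} inside a "
            f"droplet of radius {r_drop} um without exceeding the packing "
            "limit (70% occupancy)"
        )

    centers = np.empty((n, 2))
    placed = 0
    max_tries = 200 * n + 1000
    tries = 0
    # simple occupancy grid for neighbour queries
    cell = max(2.0 * float(radii.max()) + config.min_gap_um, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    while placed < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "droplet too small: rejection sampling could not place "
                f"spore {placed + 1}/{n} under the minimum-gap constraint "
                f"(min_gap_um={config.min_gap_um})"
            )
        rho = r_drop * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        x, y = cx + rho * math.cos(theta), cy + rho * math.sin(theta)
        gx, gy = int(x // cell), int(y // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), ()):
                    lim = radii[placed] + radii[j] + config.min_gap_um
                    if (x - centers[j, 0]) ** 2 + (y - centers[j, 1]) ** 2 < lim * lim:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        centers[placed] = (x, y)
        grid.setdefault((gx, gy), []).append(placed)
        placed += 1

    return ColonyState(
        time_h=0.0,
        centers_um=centers,
        radii_um=radii,
        lag_h=lags,
        germinated=np.zeros(n, dtype=bool),
        seg_coords=[],
        seg_spore=[],
        tip_pos=np.empty((0, 2)),
        tip_heading=np.empty(0),
        tip_spore=np.empty(0, dtype=np.int64),
        rng=rng,
    )


# ---------------------------------------------------------------------------
# growth


def _reflect(v: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi]."""
    span = hi - lo
    if span <= 0:
        return lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return v + lo


def advance_colony(state: ColonyState, to_time_h: float, config: SimConfig) -> ColonyState:
    """Grow the colony forward to ``to_time_h`` (in place, also returned).

    Sub-steps are aligned to the absolute grid ``k * dt_h`` so advancing in
    one call or several calls to the same time consumes the random stream
    identically.  Per sub-step: spores whose lag has elapsed emit a germ
    tube at a uniform heading; each tip turns by a Gaussian heading
    increment (sd ``tip_angle_sd_rad * sqrt(dt)``), extends by
    ``tip_speed_um_h * dt`` and may branch as a Poisson process with rate
    ``branch_rate_per_tip_h``.  Geometry is reflected at the field border.
    """
    if to_time_h < state.time_h:
        raise ValueError(
            f"cannot advance backwards: {to_time_h} < current {state.time_h}"
        )
    dt = config.dt_h
    lo, hi = 0.0, config.field_size_um
    speed = config.tip_speed_um_h

    t = state.time_h
    while t < to_time_h - 1e-12:
        # next absolute grid point, then clamp at the target
        t_next = min(math.floor(t / dt + 1.0 + 1e-9) * dt, to_time_h)
        step = t_next - t
        rng = state.rng

        # germination: one germ tube per spore whose lag elapsed this step
        newly = np.flatnonzero(~state.germinated & (state.lag_h <= t_next))
        if newly.size:
            headings = rng.uniform(0.0, 2.0 * math.pi, size=newly.size)
            px = state.centers_um[newly, 0] + state.radii_um[newly] * np.cos(headings)
            py = state.centers_um[newly, 1] + state.radii_um[newly] * np.sin(headings)
            state.tip_pos = np.vstack([state.tip_pos, np.column_stack([px, py])])
            state.tip_heading = np.concatenate([state.tip_heading, headings])
            state.tip_spore = np.concatenate([state.tip_spore, newly])
            state.germinated[newly] = True

        m = len(state.tip_pos)
        if m:
            turn = rng.normal(0.0, config.tip_angle_sd_rad * math.sqrt(step), size=m)
            state.tip_heading = state.tip_heading + turn
            dxy = np.column_stack(
                [np.cos(state.tip_heading), np.sin(state.tip_heading)]
            ) * (speed * step)
            new_pos = state.tip_pos + dxy
            out = np.flatnonzero(
                (new_pos[:, 0] < lo) | (new_pos[:, 0] > hi)
                | (new_pos[:, 1] < lo) | (new_pos[:, 1] > hi)
            )
            for i in out:
                x0, y0 = state.tip_pos[i]
                x1 = _reflect(float(new_pos[i, 0]), lo, hi)
                y1 = _reflect(float(new_pos[i, 1]), lo, hi)
                # reflected: re-aim the heading toward the kept endpoint
                state.tip_heading[i] = math.atan2(y1 - y0, x1 - x0)
                new_pos[i] = (x1, y1)
            state.seg_coords.extend(
                zip(state.tip_pos[:, 0], state.tip_pos[:, 1],
                    new_pos[:, 0], new_pos[:, 1])
            )
            state.seg_spore.extend(int(s) for s in state.tip_spore)
            state.tip_pos = new_pos

            # branching (suppressed once the tip population saturates)
            p = 1.0 - math.exp(-config.branch_rate_per_tip_h * step)
            branch = rng.uniform(size=m) < p
            if m >= config.max_active_tips:
                branch[:] = False
            idx = np.flatnonzero(branch)
            if idx.size:
                side = rng.choice([-1.0, 1.0], size=idx.size)
                dtheta = rng.normal(math.radians(60.0), 0.2, size=idx.size)
                state.tip_pos = np.vstack([state.tip_pos, state.tip_pos[idx]])
                state.tip_heading = np.concatenate(
                    [state.tip_heading, state.tip_heading[idx] + side * dtheta]
                )
                state.tip_spore = np.concatenate(
                    [state.tip_spore, state.tip_spore[idx]]
                )
        t = t_next
        state.time_h = t

    state.time_h = to_time_h
    return state


# ---------------------------------------------------------------------------
# rendering


def rasterize_mask(state: ColonyState, config: SimConfig) -> np.ndarray:
    """True foreground mask: spore discs plus hyphal segments at full width."""
    n_px = config.field_size_px
    px = config.px_size_um
    mask = np.zeros((n_px, n_px), dtype=bool)

    for (x, y), r in zip(state.centers_um, state.radii_um):
        rr, cc = skdraw.disk(
            (y / px, x / px), max(r / px, 0.6), shape=mask.shape
        )
        mask[rr, cc] = True

    if state.seg_coords:
        centerline = np.zeros_like(mask)
        coords = np.asarray(state.seg_coords) / px
        for x0, y0, x1, y1 in coords:
            rr, cc = skdraw.line(
                int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
            )
            keep = (rr >= 0) & (rr < n_px) & (cc >= 0) & (cc < n_px)
            centerline[rr[keep], cc[keep]] = True
        w_px = max(int(round(config.hypha_width_um / px)), 1)
        dil = (w_px - 1) // 2
        if dil > 0:
            centerline = ndimage.binary_dilation(
                centerline, structure=ndimage.generate_binary_structure(2, 2),
                iterations=dil,
            )
        mask |= centerline
    return mask


def rasterize_frame(
    state: ColonyState, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render (grayscale uint8 frame, true boolean mask) for the current state.

    Grayscale = two-level image (background/foreground levels) times a
    multiplicative illumination gradient, plus additive Gaussian sensor
    noise.  With ``noise_sd=0`` and ``illum_gradient_amp=0`` the grayscale
    is exactly two-valued and its upper level support equals the mask.
    """
    mask = rasterize_mask(state, config)
    n = config.field_size_px
    img = np.where(
        mask, float(config.foreground_level), float(config.background_level)
    )
    if config.illum_gradient_amp > 0:
        yy, xx = np.mgrid[0:n, 0:n]
        ramp = ((xx + yy) / (2.0 * max(n - 1, 1)) - 0.5) * 2.0  # [-1, 1] diagonal
        img = img * (1.0 + config.illum_gradient_amp * ramp)
    if config.noise_sd > 0:
        if rng is None:
            rng = state.rng
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def tile_layout(frame_size_px: int, n_tiles: int, overlap_frac: float) -> tuple[int, np.ndarray]:
    """Tile width and nominal offsets covering ``frame_size_px`` with the
    requested fractional overlap between neighbours."""
    if n_tiles == 1:
        return frame_size_px, np.array([0])
    tw = math.ceil(frame_size_px / (1.0 + (n_tiles - 1) * (1.0 - overlap_frac)))
    offsets = np.rint(
        np.arange(n_tiles) * (frame_size_px - tw) / (n_tiles - 1)
    ).astype(int)
    if tw > frame_size_px:
        raise ValueError(
            f"tile grid inconsistent with frame: tile width {tw} exceeds "
            f"frame size {frame_size_px}"
        )
    return tw, offsets


def render_tiles(
    frame: np.ndarray,
    config: SimConfig,
    time_h: float = 0.0,
    offset_jitter_px: int = 0,
    intensity_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TileSet:
    """Cut a frame into the configured overlapping tile grid.

    Optional per-tile intensity scaling and +-k px offset jitter emulate
    stage/illumination imperfections for registration testing; the
    manifest keeps the *nominal* offsets, the actual cut positions go to
    ``true_offsets``.
    """
    rows, cols = config.tile_grid
    h, w = frame.shape
    tile_h, off_y = tile_layout(h, rows, config.overlap_frac)
    tile_w, off_x = tile_layout(w, cols, config.overlap_frac)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    tiles = []
    nominal = []
    true_off = []
    for r in range(rows):
        for c in range(cols):
            oy, ox = int(off_y[r]), int(off_x[c])
            ty, tx = oy, ox
            if offset_jitter_px > 0:
                ty = int(
                    np.clip(oy + rng.integers(-offset_jitter_px, offset_jitter_px + 1),
                            0, h - tile_h)
                )
                tx = int(
                    np.clip(ox + rng.integers(-offset_jitter_px, offset_jitter_px + 1),
                            0, w - tile_w)
                )
            tile = frame[ty : ty + tile_h, tx : tx + tile_w].astype(np.float64)
            if intensity_jitter > 0:
                tile = tile * (1.0 + rng.normal(0.0, intensity_jitter))
            tiles.append(np.clip(np.rint(tile), 0, 255).astype(np.uint8))
            nominal.append((oy, ox))
            true_off.append((ty, tx))
    return TileSet(
        tiles=tiles,
        nominal_offsets=np.asarray(nominal, dtype=int),
        grid=(rows, cols),
        time_h=time_h,
        px_size_um=config.px_size_um,
        true_offsets=np.asarray(true_off, dtype=int),
    )


def generate_series(
    config: SimConfig,
    offset_jitter_px: int = 0,
    intensity_jitter: float = 0.0,
) -> tuple[list[TileSet], GroundTruth]:
    """Simulate one culture replicate: a TileSet per frame time plus ground truth.

    Bit-identical outputs for a fixed config (all stochastic draws come
    from one generator seeded with ``config.seed``).
    """
    state = init_spore_field(config)
    noise_rng = np.random.default_rng(config.seed + 7)
    tile_rng = np.random.default_rng(config.seed + 11)

    tilesets: list[TileSet] = []
    truths: list[FrameTruth] = []
    areas = math.pi * state.radii_um**2
    centers = state.centers_um.copy()
    lags = state.lag_h.copy()

    for t in config.frame_times_h:
        advance_colony(state, t, config)
        frame, mask = rasterize_frame(state, config, rng=noise_rng)
        labels = skmeasure.label(mask, connectivity=2)
        truths.append(
            FrameTruth(
                time_h=t,
                mask=mask,
                n_objects=int(labels.max()),
                occupied_px=int(mask.sum()),
                germinated_count=int(np.count_nonzero(state.lag_h <= t)),
            )
        )
        tilesets.append(
            render_tiles(
                frame,
                config,
                time_h=t,
                offset_jitter_px=offset_jitter_px,
                intensity_jitter=intensity_jitter,
                rng=tile_rng,
            )
        )
    truth = GroundTruth(centers_um=centers, areas_um2=areas, lag_h=lags, frames=truths)
    return tilesets, truth
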