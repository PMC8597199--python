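"""End-to-end orchestration: simulate -> stitch -> segment -> measure -> fit.

A :class:`RunConfig` fully determines one culture replicate run (mode,
simulator settings, processing parameters, fit windows, output
directory, seed); runs with the same config are byte-identical.  Every
run writes a machine-readable log of all parameters that affect the
numbers, and (optionally) tiles, mosaics and masks as TIFF with
provenance sidecars.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .growthstats import (
    EARLY_WINDOW,
    LATE_WINDOW,
    AdditivityReport,
    CoalescenceSeries,
    GrowthFit,
    additivity,
    coalescence,
    fit_exponential_window,
    fit_linear_window,
    replicate_mean,
)
from .imgproc import ProcessParams, process_mosaic, stitch_tiles
from .morphometry import FrameMetrics, frame_metrics
from .simulate import GroundTruth, SimConfig, TileSet, generate_series

__all__ = ["RunConfig", "CultureResult", "ExperimentReport", "run_culture", "run_experiment"]

MODES = ("simulate", "analyze", "end-to-end")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one culture-replicate run."""

    mode: str = "end-to-end"
    sim: SimConfig = field(default_factory=SimConfig)
    process: ProcessParams = field(default_factory=ProcessParams)
    refine_stitch: bool = False
    max_shift_px: int = 5
    blend: str = "feather"
    germination_area_factor: float = 2.0
    germination_ecc_min: float = 0.85
    early_window: tuple[float, float] = EARLY_WINDOW
    late_window: tuple[float, float] = LATE_WINDOW
    diameter_method: str = "feret"
    # particle-size floor against residual noise specks; well below the
    # ~560 um^2 resting-spore area so no real object is dropped
    min_object_area_um2: float = 100.0
    outdir: str | None = None
    write_images: bool = False
    label: str = "A"
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "analyze" and self.outdir is None:
            raise ValueError("analyze mode requires outdir pointing at tile data")

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["frame_times_h"] = list(self.sim.frame_times_h)
        d["sim"]["tile_grid"] = list(self.sim.tile_grid)
        d["early_window"] = list(self.early_window)
        d["late_window"] = list(self.late_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "frame_times_h" in sim:
            sim["frame_times_h"] = tuple(sim["frame_times_h"])
        if "tile_grid" in sim:
            sim["tile_grid"] = tuple(sim["tile_grid"])
        proc = dict(d.pop("process", {}))
        for key in ("early_window", "late_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(sim=SimConfig(**sim), process=ProcessParams(**proc), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class CultureResult:
    """Everything measured for one culture replicate."""

    label: str
    replicate: int
    metrics: list                      # list[FrameMetrics]
    object_tables: list                # list[pd.DataFrame]
    baseline_spore_area_um2: float
    coalescence: CoalescenceSeries
    fit_mu1: GrowthFit | None
    fit_mu2: GrowthFit | None
    fit_v: GrowthFit | None
    truth: GroundTruth | None = None
    warnings: list = field(default_factory=list)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": [m.time_h for m in self.metrics],
                "n_objects": [m.n_objects for m in self.metrics],
                "occupied_area_um2": [m.occupied_area_um2 for m in self.metrics],
                "colony_diameter_um": [m.colony_diameter_um for m in self.metrics],
                "germinated_count": [m.germinated_count for m in self.metrics],
            }
        )


@dataclass
class ExperimentReport:
    """Comparative report across cultures (replicate-averaged)."""

    results: dict                      # label -> list[CultureResult]
    mean_area_series: dict             # label -> (times, mean, sd)
    fits: pd.DataFrame
    additivity: AdditivityReport | None
    notes: list


def _analyze_tilesets(tilesets: list[TileSet], config: RunConfig):
    notes: list[str] = []
    masks = []
    for ts in tilesets:
        mosaic = stitch_tiles(
            ts, refine=config.refine_stitch, max_shift_px=config.max_shift_px,
            blend=config.blend,
        )
        masks.append(process_mosaic(mosaic, config.process))

    # baseline resting-spore area from the t=0 frame (median object area)
    from .morphometry import label_objects, measure_objects

    t0_table = measure_objects(
        label_objects(masks[0].mask), masks[0].px_size_um,
        min_area_um2=config.min_object_area_um2,
    )
    if len(t0_table) == 0:
        raise ValueError("no objects detected at time 0; cannot set spore baseline")
    baseline = float(t0_table["area_um2"].median())

    metrics, tables = [], []
    for bf in masks:
        m, table = frame_metrics(
            bf, baseline_spore_area_um2=baseline,
            with_diameter=bf.mask.any(), diameter_method=config.diameter_method,
            min_area_um2=config.min_object_area_um2,
            area_factor=config.germination_area_factor,
            ecc_min=config.germination_ecc_min,
        )
        metrics.append(m)
        tables.append(table)

    counts = [m.n_objects for m in metrics]
    if any(b > a for a, b in zip(counts[1:], counts[2:])):
        msg = "object count increased after t=0 (expected non-increasing coalescence)"
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    areas = [m.occupied_area_um2 for m in metrics]
    if any(b < a for a, b in zip(areas, areas[1:])):
        msg = "occupied area decreased over time (expected non-decreasing growth)"
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    return metrics, tables, baseline, notes, masks


def run_culture(config: RunConfig) -> CultureResult:
    """Run one culture replicate according to ``config.mode``.

    ``simulate`` writes tiles + ground truth and analyses them in memory;
    ``analyze`` reads previously written tiles from ``outdir``;
    ``end-to-end`` does everything in memory (writing artefacts only if
    ``outdir`` is set).
    """
    outdir = Path(config.outdir) if config.outdir else None
    truth = None

    if config.mode == "analyze":
        assert outdir is not None
        frame_dirs = sorted(p for p in outdir.glob("frame_*") if p.is_dir())
        if not frame_dirs:
            raise FileNotFoundError(
                f"analyze mode: no frame_* tile directories under {outdir}"
            )
        tilesets = [mio.read_tileset(d) for d in frame_dirs]
    else:
        tilesets, truth = generate_series(config.sim)
        if outdir is not None:
            for i, ts in enumerate(tilesets):
                mio.write_tileset(ts, outdir / f"frame_{i:02d}")
            truth.spore_table().to_csv(outdir / "ground_truth_spores.csv", index=False)

    metrics, tables, baseline, notes, masks = _analyze_tilesets(tilesets, config)
    if outdir is not None and config.write_images:
        for i, bf in enumerate(masks):
            mio.write_mask(bf, outdir / f"mask_{i:02d}.tif")

    times = np.array([m.time_h for m in metrics])
    counts = np.array([m.n_objects for m in metrics], dtype=float)
    areas = np.array([m.occupied_area_um2 for m in metrics])
    diams = np.array(
        [np.nan if m.colony_diameter_um is None else m.colony_diameter_um
         for m in metrics]
    )

    coal = coalescence(times, counts)

    def _try_fit(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as exc:
            notes.append(str(exc))
            return None

    fit1 = _try_fit(fit_exponential_window, times, areas, config.early_window)
    fit2 = _try_fit(fit_exponential_window, times, areas, config.late_window)
    good = ~np.isnan(diams)
    fitv = _try_fit(fit_linear_window, times[good], diams[good], config.late_window)

    result = CultureResult(
        label=config.label, replicate=config.replicate,
        metrics=metrics, object_tables=tables,
        baseline_spore_area_um2=baseline, coalescence=coal,
        fit_mu1=fit1, fit_mu2=fit2, fit_v=fitv, truth=truth, warnings=notes,
    )

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_metrics_csv(metrics, outdir / "frame_metrics.csv")
        log = {
            "config": config.to_dict(),
            "baseline_spore_area_um2": baseline,
            "warnings": notes,
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return result


def run_experiment(configs: dict, control: str = "A") -> ExperimentReport:
    """Run several cultures (each a list of replicate RunConfigs) and
    build the comparative report: replicate-mean occupied-area series,
    the fitted-rate table, and — when a control plus at least two other
    cultures are present — the fraction-additivity analysis."""
    if not configs:
        raise ValueError("need at least one culture")
    results: dict[str, list[CultureResult]] = {}
    for label, reps in configs.items():
        results[label] = [run_culture(c) for c in reps]

    mean_series = {}
    final_means = {}
    for label, reps in results.items():
        times = np.array([m.time_h for m in reps[0].metrics])
        stack = [
            [m.occupied_area_um2 for m in r.metrics] for r in reps
        ]
        mean, sd = replicate_mean(stack)
        mean_series[label] = (times, mean, sd)
        final_means[label] = float(mean[-1])

    rows = []
    for label, reps in results.items():
        for r in reps:
            rows.append(
                {
                    "culture": label,
                    "replicate": r.replicate,
                    "mu1_per_h": r.fit_mu1.rate if r.fit_mu1 else np.nan,
                    "mu1_r2": r.fit_mu1.r2 if r.fit_mu1 else np.nan,
                    "mu2_per_h": r.fit_mu2.rate if r.fit_mu2 else np.nan,
                    "mu2_r2": r.fit_mu2.r2 if r.fit_mu2 else np.nan,
                    "v_um_per_h": r.fit_v.rate if r.fit_v else np.nan,
                    "v_r2": r.fit_v.r2 if r.fit_v else np.nan,
                    "final_area_um2": r.metrics[-1].occupied_area_um2,
                }
            )
    fits = pd.DataFrame(rows)

    notes: list[str] = []
    report_add = None
    if control in final_means and len(final_means) >= 3:
        others = sorted(k for k in final_means if k != control)
        pairs = tuple(
            (others[i], others[j])
            for i in range(len(others))
            for j in range(i + 1, len(others))
        )
        report_add = additivity(
            final_means, control=control,
            reference=others[0], pairs=pairs,
            time_h=float(list(mean_series.values())[0][0][-1]),
        )
    else:
        notes.append(
            "additivity analysis omitted: needs the control culture plus at "
            "least two fraction cultures"
        )
    return ExperimentReport(
        results=results, mean_area_series=mean_series, fits=fits,
        additivity=report_add, notes=notes,
    )
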