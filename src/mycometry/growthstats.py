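"""Growth statistics: germination, coalescence, rate fits, additivity.

Converts per-frame morphometrics into the four growth measurements used
to compare cultures:

* germination percentage and germination rate (spores/h) per interval,
* coalescence — the percentage of initially counted objects remaining,
* occupied-area growth rate mu (1/h) from an exponential (log-linear OLS)
  fit over a time window,
* radial expansion speed v (um/h) from a linear OLS fit of colony
  diameter over a time window,

plus the substrate-fraction additivity analysis: control-subtracted
occupied areas and their pairwise sums.

Percentages and spore/h rates are conventionally reported rounded to
integers and mu to three decimals; every function returns full-precision
values and leaves rounding to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GerminationSeries",
    "CoalescenceSeries",
    "GrowthFit",
    "AdditivityReport",
    "germination_percentage",
    "germination_rate",
    "germination_series",
    "coalescence",
    "fit_exponential_window",
    "fit_linear_window",
    "additivity",
    "replicate_mean",
]

#: Default fit windows (hours): early/late occupied-area, radial expansion.
EARLY_WINDOW = (23.0, 29.0)
LATE_WINDOW = (29.0, 52.0)


@dataclass
class GerminationSeries:
    times_h: np.ndarray
    n_total_spores: int
    pct_germinated: np.ndarray          # per time point
    rate_spores_per_h: np.ndarray       # per interval (t[i-1] -> t[i]), t[-1]=0


@dataclass
class CoalescenceSeries:
    times_h: np.ndarray
    n_objects: np.ndarray
    pct_remaining: np.ndarray           # 100 * N(t) / N(0)


@dataclass
class GrowthFit:
    model: str                          # "exponential" | "linear"
    window: tuple                       # (t_start, t_end, n_points)
    rate: float                         # mu (1/h) or v (um/h)
    intercept: float                    # ln(A) at t=0, or diameter at t=0
    r2: float


@dataclass
class AdditivityReport:
    """Control-subtracted occupied areas at a common time point."""

    time_h: float
    control: str
    mean_areas_um2: dict
    minus_control: dict                 # X - control for every other culture
    sum_pairs: dict                     # e.g. "(C-A)+(D-A)" -> value
    ratio_vs_reference: dict            # ((X-ctrl)) / (ref-ctrl)


def germination_percentage(germinated_count: int, n_total: int) -> float:
    """100 * germinated / total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= germinated_count <= n_total):
        raise ValueError("germinated_count must lie in [0, n_total]")
    return 100.0 * germinated_count / n_total


def germination_rate(
    pct_t1: float, pct_t2: float, n_total: int, t1_h: float, t2_h: float
) -> float:
    """Newly germinated spores per hour over (t1, t2].

    ((pct2 - pct1)/100 * N0) / (t2 - t1); the first observation interval
    uses pct(0) = 0.
    """
    if t2_h <= t1_h:
        raise ValueError("t2_h must exceed t1_h")
    if pct_t2 < pct_t1:
        raise ValueError("germination percentage cannot decrease")
    return (pct_t2 - pct_t1) / 100.0 * n_total / (t2_h - t1_h)


def germination_series(
    times_h, pct_germinated, n_total: int
) -> GerminationSeries:
    """Rates for every consecutive interval of a germination profile.

    ``times_h`` excludes time 0; the first interval runs from (0 h, 0 %).
    """
    times = np.asarray(times_h, dtype=float)
    pcts = np.asarray(pct_germinated, dtype=float)
    if times.shape != pcts.shape or times.ndim != 1:
        raise ValueError("times and percentages must be 1-D and aligned")
    t_ext = np.concatenate([[0.0], times])
    p_ext = np.concatenate([[0.0], pcts])
    rates = np.array(
        [
            germination_rate(p_ext[i], p_ext[i + 1], n_total, t_ext[i], t_ext[i + 1])
            for i in range(len(times))
        ]
    )
    return GerminationSeries(
        times_h=times, n_total_spores=int(n_total),
        pct_germinated=pcts, rate_spores_per_h=rates,
    )


def coalescence(times_h, n_objects) -> CoalescenceSeries:
    """Percentage of initially counted objects remaining at each frame."""
    times = np.asarray(times_h, dtype=float)
    counts = np.asarray(n_objects, dtype=float)
    if counts.ndim != 1 or counts.shape != times.shape:
        raise ValueError("times and counts must be 1-D and aligned")
    if counts[0] <= 0:
        raise ValueError("initial object count must be positive")
    return CoalescenceSeries(
        times_h=times, n_objects=counts, pct_remaining=100.0 * counts / counts[0]
    )


def _window_points(times, values, window):
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    t0, t1 = float(window[0]), float(window[1])
    sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    return t[sel], v[sel]


def fit_exponential_window(times_h, areas_um2, window=EARLY_WINDOW) -> GrowthFit:
    """Exponential growth rate mu (1/h) of occupied area over a window.

    Ordinary least squares of ln(area) against time; R^2 is computed on
    the log scale (1 - SSres/SStot of ln area).
    """
    t, a = _window_points(times_h, areas_um2, window)
    if len(t) < 3:
        raise ValueError(f"need >= 3 points inside window {window}, got {len(t)}")
    if np.any(a <= 0):
        raise ValueError("areas must be positive for an exponential fit")
    res = stats.linregress(t, np.log(a))
    return GrowthFit(
        model="exponential",
        window=(float(window[0]), float(window[1]), int(len(t))),
        rate=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def fit_linear_window(times_h, diameters_um, window=LATE_WINDOW) -> GrowthFit:
    """Radial expansion speed v (um/h): OLS slope of colony diameter."""
    t, d = _window_points(times_h, diameters_um, window)
    if len(t) < 2:
        raise ValueError(f"need >= 2 points inside window {window}, got {len(t)}")
    res = stats.linregress(t, d)
    r2 = 1.0 if len(t) == 2 else float(res.rvalue**2)
    return GrowthFit(
        model="linear",
        window=(float(window[0]), float(window[1]), int(len(t))),
        rate=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
    )


def additivity(
    mean_areas_um2: dict,
    control: str = "A",
    reference: str = "B",
    pairs: tuple = (("C", "D"), ("C", "E")),
    time_h: float = 52.0,
) -> AdditivityReport:
    """Substrate-fraction additivity of final occupied areas.

    Subtracts the control culture's area from every other culture and
    sums the control-subtracted fraction cultures pairwise; if growth on
    fractions is additive, a pair sum approaches the control-subtracted
    reference (whole substrate) value.
    """
    if control not in mean_areas_um2:
        raise ValueError(f"control culture {control!r} missing")
    ctrl = float(mean_areas_um2[control])
    minus = {
        k: float(v) - ctrl for k, v in mean_areas_um2.items() if k != control
    }
    sums = {}
    for x, y in pairs:
        if x in minus and y in minus:
            sums[f"({x}-{control})+({y}-{control})"] = minus[x] + minus[y]
    ratios = {}
    if reference in minus and minus[reference] != 0:
        ref = minus[reference]
        ratios = {k: v / ref for k, v in minus.items() if k != reference}
        for key, v in sums.items():
            ratios[key] = v / ref
    return AdditivityReport(
        time_h=time_h, control=control, mean_areas_um2=dict(mean_areas_um2),
        minus_control=minus, sum_pairs=sums, ratio_vs_reference=ratios,
    )


def replicate_mean(series_list) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean and single-SD envelope across aligned replicates."""
    arr = np.asarray(series_list, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need >= 1 aligned replicate series")
    return arr.mean(axis=0), arr.std(axis=0, ddof=0)
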