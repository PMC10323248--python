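"""Statistical comparison of temperature cohorts.

Three families of tests:

* a trajectory-level repeated-measures ANOVA of total energy across
  relative developmental time, with per-gridpoint Tukey HSD post hoc
  comparisons reported as contiguous significant regions;
* band-wise Kruskal-Wallis tests of window-mean energy across the 60
  frequency bands under one Bonferroni family (alpha / 60);
* per-event Kruskal-Wallis tests of absolute event timings with an
  accelerated / delayed / unchanged direction call.

The repeated-measures construction treats temperature as the within
factor paired across the grid points of the cohort-mean trajectories, so
a complete default 100-point grid yields df (1, 99); with two levels the
F statistic is the square of the paired t statistic over grid points.
Tukey's HSD is computed through the studentized-range distribution, so it
generalises beyond two groups; with two groups it coincides with the
pooled-variance two-sample comparison.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import BAND_WIDTH_HZ, N_BANDS
from .synthetic import EVENT_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "TrajectoryTest",
    "BandTestSet",
    "EventTest",
    "EventTimingTest",
    "trajectory_anova",
    "pointwise_posthoc",
    "tukey_two_group",
    "bandwise_kw",
    "event_timing_kw",
    "kruskal_two_sample",
]


@dataclass(frozen=True)
class Region:
    """A contiguous run of grid points with a significant group difference."""

    start_index: int
    end_index: int  # inclusive
    rel_start: float
    rel_end: float
    direction: str  # "increased" | "decreased" (group B relative to A)
    min_p: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.rel_start + self.rel_end)


@dataclass
class TrajectoryTest:
    """Repeated-measures comparison of two total-energy trajectories."""

    F: float
    df_num: int
    df_den: int
    p: float
    n_points: int
    pointwise_p: np.ndarray | None = None
    regions: list = field(default_factory=list)
    significant_region: frozenset = frozenset()


def trajectory_anova(grid_a: np.ndarray, grid_b: np.ndarray) -> TrajectoryTest:
    """Two-level repeated-measures ANOVA of cohort-mean trajectories.

    ``grid_a`` and ``grid_b`` are (n_embryos, n_grid) arrays on the same
    relative-time grid (NaN = missing). Temperature is the within factor
    and the grid points are the repeated units; grid points missing in
    either cohort mean are dropped pairwise with the error df reduced
    accordingly (a complete 100-point grid gives df (1, 99)).
    """
    grid_a = np.atleast_2d(np.asarray(grid_a, dtype=float))
    grid_b = np.atleast_2d(np.asarray(grid_b, dtype=float))
    if grid_a.shape[0] < 2 or grid_b.shape[0] < 2:
        raise ValueError("each cohort needs at least 2 embryos")
    if grid_a.shape[1] != grid_b.shape[1]:
        raise ValueError("cohorts must share the same grid")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid columns
        mean_a = np.nanmean(grid_a, axis=0)
        mean_b = np.nanmean(grid_b, axis=0)
    ok = np.isfinite(mean_a) & np.isfinite(mean_b)
    n_points = int(ok.sum())
    if n_points < 2:
        raise ValueError("fewer than 2 grid points usable in both cohorts")
    d = mean_a[ok] - mean_b[ok]
    md = d.mean()
    ss = float(((d - md) ** 2).sum())
    df_num, df_den = 1, n_points - 1
    if ss == 0.0:
        if md == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = math.inf, 0.0
    else:
        F = md**2 / (ss / df_den / n_points)
        p = float(stats.f.sf(F, df_num, df_den))
    return TrajectoryTest(F=float(F), df_num=df_num, df_den=df_den, p=p, n_points=n_points)


def tukey_two_group(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tukey HSD comparison of two groups via the studentized range.

    Returns (q statistic, p value). With two groups this equals the
    pooled-variance two-sample comparison: q = sqrt(2) * |t|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 values")
    df = nx + ny - 2
    ms_within = (np.var(x, ddof=1) * (nx - 1) + np.var(y, ddof=1) * (ny - 1)) / df
    diff = abs(x.mean() - y.mean())
    if ms_within == 0.0:
        return (0.0, 1.0) if diff == 0.0 else (math.inf, 0.0)
    # Tukey-Kramer standard error for unequal group sizes
    q = diff / math.sqrt(ms_within / 2.0 * (1.0 / nx + 1.0 / ny))
    p = float(stats.studentized_range.sf(q, 2, df))
    return float(q), p


def pointwise_posthoc(
    grid_a: np.ndarray,
    grid_b: np.ndarray,
    alpha: float = 0.05,
    rel_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, list[Region], frozenset]:
    """Tukey HSD between temperatures at every relative-time grid point.

    Returns the per-gridpoint p values (NaN where a point was skipped for
    having fewer than 2 embryos in either group), the contiguous
    significant regions (split where the direction flips) and the set of
    significant grid indices.
    """
    grid_a = np.atleast_2d(np.asarray(grid_a, dtype=float))
    grid_b = np.atleast_2d(np.asarray(grid_b, dtype=float))
    if grid_a.shape[1] != grid_b.shape[1]:
        raise ValueError("cohorts must share the same grid")
    n_grid = grid_a.shape[1]
    rel = np.linspace(0.0, 1.0, n_grid) if rel_grid is None else np.asarray(rel_grid)
    pvals = np.full(n_grid, np.nan)
    direction = np.zeros(n_grid)
    for g in range(n_grid):
        x = grid_a[:, g]
        y = grid_b[:, g]
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size < 2 or y.size < 2:
            logger.info("grid point %d skipped (<2 embryos in a group)", g)
            continue
        _, pvals[g] = tukey_two_group(x, y)
        direction[g] = np.sign(y.mean() - x.mean())
    significant = np.flatnonzero(np.nan_to_num(pvals, nan=1.0) < alpha)
    regions: list[Region] = []
    for g in significant:
        if regions and g == regions[-1].end_index + 1 and direction[g] == direction[regions[-1].end_index]:
            last = regions[-1]
            regions[-1] = Region(
                last.start_index,
                int(g),
                last.rel_start,
                float(rel[g]),
                last.direction,
                min(last.min_p, float(pvals[g])),
            )
        else:
            regions.append(
                Region(
                    int(g),
                    int(g),
                    float(rel[g]),
                    float(rel[g]),
                    "increased" if direction[g] > 0 else "decreased",
                    float(pvals[g]),
                )
            )
    return pvals, regions, frozenset(int(g) for g in significant)


def kruskal_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H and p for two samples; degenerate ties give H=0, p=1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(x, y)
    return float(h), float(p)


@dataclass
class BandTestSet:
    """Band-wise Kruskal-Wallis results for one physiological window."""

    H: np.ndarray  # (60,)
    p: np.ndarray  # (60,)
    corrected_alpha: float
    significant_bands: frozenset
    directions: tuple  # per band: "increased" | "decreased" | "unchanged"
    hz_ranges: tuple  # contiguous significant bands as (low, high) Hz


def _contiguous_hz_ranges(bands: list[int]) -> tuple:
    ranges = []
    for k in sorted(bands):
        low = round(k * BAND_WIDTH_HZ, 1)
        high = round((k + 1) * BAND_WIDTH_HZ, 1)
        if ranges and math.isclose(ranges[-1][1], low):
            ranges[-1] = (ranges[-1][0], high)
        else:
            ranges.append((low, high))
    return tuple(ranges)


def bandwise_kw(
    window_means_a: np.ndarray | pd.DataFrame,
    window_means_b: np.ndarray | pd.DataFrame,
    family_alpha: float = 0.05,
) -> BandTestSet:
    """One Kruskal-Wallis test per frequency band under a Bonferroni family.

    Inputs are per-embryo window-mean energy vectors, one row per embryo,
    60 columns. The per-test threshold is ``family_alpha / 60``
    (0.05 / 60 = 0.00083 at 2 s.f.); the direction is the sign of the
    median difference of group B relative to group A.
    """
    a = np.asarray(window_means_a, dtype=float)
    b = np.asarray(window_means_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != N_BANDS or b.shape[1] != N_BANDS:
        raise ValueError(f"window means must be 2-D with {N_BANDS} columns")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 embryos")
    H = np.zeros(N_BANDS)
    p = np.ones(N_BANDS)
    directions = []
    for k in range(N_BANDS):
        H[k], p[k] = kruskal_two_sample(a[:, k], b[:, k])
        delta = np.median(b[:, k]) - np.median(a[:, k])
        directions.append("increased" if delta > 0 else "decreased" if delta < 0 else "unchanged")
    corrected = family_alpha / N_BANDS
    sig = [k for k in range(N_BANDS) if p[k] < corrected]
    return BandTestSet(
        H=H,
        p=p,
        corrected_alpha=corrected,
        significant_bands=frozenset(sig),
        directions=tuple(directions),
        hz_ranges=_contiguous_hz_ranges(sig),
    )


@dataclass(frozen=True)
class EventTest:
    H: float
    p: float
    direction: str  # "accelerated" | "delayed" | "unchanged" (group B vs A)


@dataclass
class EventTimingTest:
    """Per-event Kruskal-Wallis comparison of absolute timings."""

    tests: dict
    skipped: tuple = ()


def event_timing_kw(events_a: pd.DataFrame, events_b: pd.DataFrame) -> EventTimingTest:
    """Compare event timings between cohorts, event by event.

    ``events_a``/``events_b`` are wide tables (one row per embryo, one
    column per event, NaN = not scored). Direction is called from the
    median: group B earlier than group A means "accelerated". Events with
    fewer than 2 scored embryos in either group are skipped and logged.
    """
    candidates = [e for e in (*EVENT_NAMES, "hatch") if e in events_a.columns and e in events_b.columns]
    tests: dict[str, EventTest] = {}
    skipped = []
    for event in candidates:
        x = events_a[event].dropna().to_numpy(dtype=float)
        y = events_b[event].dropna().to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            logger.warning("event %r skipped: fewer than 2 scored embryos in a group", event)
            skipped.append(event)
            continue
        h, p = kruskal_two_sample(x, y)
        delta = np.median(y) - np.median(x)
        direction = "accelerated" if delta < 0 else "delayed" if delta > 0 else "unchanged"
        tests[event] = EventTest(H=h, p=p, direction=direction)
    return EventTimingTest(tests=tests, skipped=tuple(skipped))
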