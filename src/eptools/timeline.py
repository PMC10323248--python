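"""Developmental event timings and relative-time normalisation.

Absolute clip times (hours post-4-cell) are rescaled by each embryo's
own hatch time onto relative developmental time in [0, 1], clips are
labelled with the physiological window they fall in (delimited by that
embryo's *own* event order, so heterochronic species yield different
window sequences), and total-energy trajectories are resampled onto a
common relative-time grid for cohort comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import BAND_WIDTH_HZ, N_BANDS, EPTSpectrum
from .synthetic import EVENT_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "PRE_WINDOW",
    "PostHatchError",
    "EmbryoRecord",
    "to_relative_time",
    "assign_windows",
    "window_mean_spectra",
    "resample_to_grid",
    "cohort_grid",
    "events_frame",
]

#: window label for clips before the first scored onset
PRE_WINDOW = "pre_rotation"


class PostHatchError(ValueError):
    """A clip time lies after the embryo's hatch time."""


def to_relative_time(clip_time: float, hatch: float) -> float:
    """Rescale an absolute clip time by the embryo's hatch time onto [0, 1]."""
    if not hatch > 0:
        raise ValueError("hatch must be positive")
    if clip_time < 0:
        raise ValueError("clip_time must be non-negative")
    if clip_time > hatch:
        raise PostHatchError(f"clip at {clip_time} h is after hatch at {hatch} h")
    return clip_time / hatch


@dataclass
class EmbryoRecord:
    """An embryo's spectrum time series plus its event timings.

    ``events`` maps event names to hours post-4-cell and must contain
    "hatch"; the four onsets may be partially missing (windows shrink).
    Spectra with clip times after hatch are excluded on construction and
    kept in ``excluded_post_hatch`` for audit.
    """

    embryo_id: str
    species: str
    temperature_label: str
    spectra: list
    events: dict
    excluded_post_hatch: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if "hatch" not in self.events or not self.events["hatch"] > 0:
            raise ValueError("events must include a positive hatch time")
        hatch = float(self.events["hatch"])
        for name, t in self.events.items():
            if name != "hatch" and not 0 < t <= hatch:
                raise ValueError(f"event {name} at {t} h outside (0, hatch]")
        kept = []
        for spec in self.spectra:
            if spec.clip_time > hatch:
                self.excluded_post_hatch.append(spec)
            else:
                spec.rel_time = to_relative_time(spec.clip_time, hatch)
                kept.append(spec)
        if self.excluded_post_hatch:
            logger.info(
                "embryo %s: excluded %d post-hatch clip(s)",
                self.embryo_id,
                len(self.excluded_post_hatch),
            )
        times = [s.clip_time for s in kept]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("spectra clip times must be strictly increasing")
        self.spectra = kept

    @property
    def hatch(self) -> float:
        return float(self.events["hatch"])

    @property
    def event_order(self) -> tuple[str, ...]:
        """The embryo's scored onsets, in its own temporal order."""
        present = [e for e in EVENT_NAMES if e in self.events]
        return tuple(sorted(present, key=self.events.get))


def assign_windows(record: EmbryoRecord) -> list[str]:
    """Label each spectrum with its physiological window.

    A clip belongs to the window opened by the most recent onset event at
    or before its clip time; clips before the first onset are labelled
    ``pre_rotation``. Windows therefore partition each embryo's
    post-onset clips exactly once, following the embryo's own event order
    (heterochronic orders yield different window sequences).
    """
    order = record.event_order
    if not order:
        logger.info("embryo %s: no scored onsets; all clips pre_rotation", record.embryo_id)
    labels = []
    for spec in record.spectra:
        current = PRE_WINDOW
        for event in order:
            if spec.clip_time >= record.events[event]:
                current = event
            else:
                break
        labels.append(current)
    return labels


def window_mean_spectra(records: list[EmbryoRecord], window: str) -> pd.DataFrame:
    """Per-embryo mean 60-band energy vectors within one window.

    Embryos with no clips in the window are omitted (never zero-filled).
    Returns a DataFrame indexed by embryo_id with one column per band
    (column label = band lower edge in Hz).
    """
    cols = np.round(np.arange(N_BANDS) * BAND_WIDTH_HZ, 1)
    rows, index = [], []
    for rec in records:
        labels = assign_windows(rec)
        in_window = [s.band_energy for s, lab in zip(rec.spectra, labels) if lab == window]
        if not in_window:
            logger.info("embryo %s: no clips in window %r", rec.embryo_id, window)
            continue
        rows.append(np.mean(in_window, axis=0))
        index.append(rec.embryo_id)
    if not rows:
        raise ValueError(f"window {window!r} is empty for the whole cohort")
    return pd.DataFrame(rows, index=pd.Index(index, name="embryo_id"), columns=cols)


def resample_to_grid(
    record: EmbryoRecord,
    n_grid: int = 100,
    max_gap_h: float = 3.0,
    boundary_tol: float | None = None,
) -> np.ndarray:
    """Total energy linearly interpolated onto an even relative-time grid.

    Grid points outside the observed relative-time range are NaN, except
    that an endpoint within ``boundary_tol`` (default: one grid spacing)
    of the nearest observation takes that observation's value — the last
    pre-hatch clip sits a fraction of a grid step below rel_time 1.0, and
    holding its value there keeps the grid complete without extrapolating
    any trend. Grid points inside an observation gap longer than
    ``max_gap_h`` hours are NaN rather than silently interpolated.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    rel = np.array([s.rel_time for s in record.spectra], dtype=float)
    te = np.array([s.total_energy for s in record.spectra], dtype=float)
    if rel.size < 2:
        raise ValueError("need at least 2 spectra to resample")
    grid = np.linspace(0.0, 1.0, n_grid)
    tol = 1.0 / (n_grid - 1) if boundary_tol is None else boundary_tol
    out = np.interp(grid, rel, te)  # clamps at the ends == boundary hold
    out[(grid < rel[0] - tol) | (grid > rel[-1] + tol)] = np.nan
    gap_h = np.diff(rel) * record.hatch
    for i in np.flatnonzero(gap_h > max_gap_h):
        inside = (grid > rel[i]) & (grid < rel[i + 1])
        out[inside] = np.nan
    return out


def cohort_grid(records: list[EmbryoRecord], n_grid: int = 100, **kwargs) -> np.ndarray:
    """Stack per-embryo gridded trajectories into an (n_embryos, n_grid) array."""
    return np.stack([resample_to_grid(r, n_grid=n_grid, **kwargs) for r in records])


def events_frame(records: list[EmbryoRecord]) -> pd.DataFrame:
    """Wide event-timing table (one row per embryo, one column per event)."""
    return pd.DataFrame([dict(r.events) for r in records], index=[r.embryo_id for r in records])
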