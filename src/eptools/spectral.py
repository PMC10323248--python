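"""Energy proxy trait (EPT) computation.

Each clip's mean-brightness trace is decomposed with Welch's method and
the resulting one-sided power spectral density is binned into 60
temporal-frequency bands of 0.1 Hz, band k covering [0.1*k, 0.1*(k+1)) Hz
for k = 0..59. Band energy is density times grid spacing summed per band
(rectangle rule), so the 60 bands partition the DC-excluded integrated
PSD below 6 Hz exactly and total energy is their exact sum.

The default Welch configuration uses 10-second segments (so the analysis
grid spacing is exactly 0.1 Hz and grid frequencies coincide with band
edges), a rectangular taper and per-segment linear detrending. With this
grid, a periodic signal whose frequency is a multiple of 0.1 Hz completes
an integer number of cycles per segment and its power lands entirely in
the band that owns that frequency; a Hann taper or other segment lengths
can be configured when matching other software.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import BrightnessTrace

logger = logging.getLogger(__name__)

__all__ = [
    "N_BANDS",
    "BAND_WIDTH_HZ",
    "FMAX_HZ",
    "WelchConfig",
    "EPTSpectrum",
    "band_edges",
    "welch_psd",
    "bin_bands",
    "total_energy",
    "compute_spectrum",
    "spectra_for_embryo",
    "BandEnergyExtractor",
]

N_BANDS = 60
BAND_WIDTH_HZ = 0.1
FMAX_HZ = N_BANDS * BAND_WIDTH_HZ  # 6.0

#: default segment duration in seconds; 10 s gives a 0.1-Hz analysis grid
DEFAULT_SEGMENT_SECONDS = 10.0

_DETREND = {"none": False, "constant": "constant", "linear": "linear"}


def band_edges() -> np.ndarray:
    """The 61 band edges, 0.0, 0.1, ..., 6.0 Hz."""
    return np.arange(N_BANDS + 1) * BAND_WIDTH_HZ


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings.

    ``segment_length`` is in frames; None resolves to 10 s of frames at
    the trace's own rate, keeping the frequency grid aligned with the
    0.1-Hz band edges at any acquisition rate.
    """

    segment_length: int | None = None
    overlap_fraction: float = 0.5
    taper: str = "boxcar"
    detrend: str = "linear"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.detrend not in _DETREND:
            raise ValueError("detrend must be 'none', 'constant' or 'linear'")
        if self.segment_length is not None and self.segment_length < 2:
            raise ValueError("segment_length must be at least 2 frames")

    def resolve_nperseg(self, fps: float) -> int:
        if self.segment_length is not None:
            return int(self.segment_length)
        return int(round(DEFAULT_SEGMENT_SECONDS * fps))


def _welch_matrix(values: np.ndarray, fps: float, cfg: WelchConfig):
    """Welch PSD along the last axis; values may be 1-D or 2-D."""
    if not np.all(np.isfinite(values)):
        raise ValueError("trace contains non-finite values")
    nperseg = cfg.resolve_nperseg(fps)
    if values.shape[-1] < nperseg:
        raise ValueError(
            f"trace too short for Welch segments ({values.shape[-1]} < {nperseg} frames)"
        )
    freqs, psd = welch(
        values,
        fs=fps,
        window=cfg.taper,
        nperseg=nperseg,
        noverlap=int(round(cfg.overlap_fraction * nperseg)),
        detrend=_DETREND[cfg.detrend],
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def welch_psd(trace: BrightnessTrace, cfg: WelchConfig | None = None):
    """One-sided Welch PSD of a trace.

    Returns
    -------
    freqs : array
        Frequency grid from 0 to fps/2, spacing fps / segment_length.
    psd : array
        Power spectral density in (grey level)^2 / Hz.
    """
    cfg = cfg or WelchConfig()
    return _welch_matrix(trace.values, trace.fps, cfg)


def _band_index(freqs: np.ndarray) -> np.ndarray:
    # half-open [0.1k, 0.1(k+1)): a grid frequency sitting (to within float
    # error) on a band edge belongs to the upper band
    return np.floor(freqs / BAND_WIDTH_HZ + 1e-6).astype(int)


def bin_bands(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Bin a PSD into the 60 0.1-Hz band energies.

    The f=0 grid point is excluded (baseline brightness is illumination,
    not physiology) and frequencies at or above 6 Hz are discarded. Band
    energy is density * grid spacing summed over the band's grid points.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.ndim != 1 or freqs.size < 2:
        raise ValueError("need a 1-D frequency grid with at least 2 points")
    if freqs[-1] < FMAX_HZ - 1e-9:
        raise ValueError(f"PSD Nyquist {freqs[-1]:.3f} Hz below the {FMAX_HZ} Hz analysis range")
    df = freqs[1] - freqs[0]
    idx = _band_index(freqs)
    keep = (freqs > 0) & (idx < N_BANDS)
    if psd.ndim == 1:
        return np.bincount(idx[keep], weights=psd[keep] * df, minlength=N_BANDS)[:N_BANDS]
    onehot = np.zeros((keep.sum(), N_BANDS))
    onehot[np.arange(keep.sum()), idx[keep]] = 1.0
    return (psd[..., keep] * df) @ onehot


@dataclass
class EPTSpectrum:
    """60 band energies for one clip; the energy proxy trait."""

    band_energy: np.ndarray
    embryo_id: str = ""
    clip_time: float = 0.0
    rel_time: float | None = None

    def __post_init__(self) -> None:
        self.band_energy = np.asarray(self.band_energy, dtype=float)
        if self.band_energy.shape != (N_BANDS,):
            raise ValueError(f"expected exactly {N_BANDS} band energies")
        if np.any(self.band_energy < 0) or not np.all(np.isfinite(self.band_energy)):
            raise ValueError("band energies must be finite and non-negative")

    @property
    def total_energy(self) -> float:
        """Exact sum of the 60 band energies."""
        return float(self.band_energy.sum())


def total_energy(spectrum: EPTSpectrum) -> float:
    """Sum of energy in all frequency bands for one time point."""
    return spectrum.total_energy


def compute_spectrum(trace: BrightnessTrace, cfg: WelchConfig | None = None) -> EPTSpectrum:
    """Welch-decompose one trace and bin it into an EPT spectrum."""
    freqs, psd = welch_psd(trace, cfg)
    return EPTSpectrum(
        bin_bands(freqs, psd),
        embryo_id=trace.embryo_id,
        clip_time=trace.clip_time,
        rel_time=None,
    )


def spectra_for_embryo(
    traces: list[BrightnessTrace | None], cfg: WelchConfig | None = None
) -> list[EPTSpectrum]:
    """One spectrum per clip of one embryo, ordered by clip time.

    Clips that failed upstream (``None`` entries) are skipped and logged
    as missing — they never contribute zeros downstream.
    """
    cfg = cfg or WelchConfig()
    present = [t for t in traces if t is not None]
    n_missing = len(traces) - len(present)
    if n_missing:
        logger.info("%d clip(s) missing and excluded", n_missing)
    if not present:
        return []
    ids = {t.embryo_id for t in present}
    if len(ids) > 1:
        raise ValueError(f"traces mix embryo ids {sorted(ids)}")
    times = [t.clip_time for t in present]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("clip times must be strictly increasing (duplicate or unordered clip)")

    # batch same-shape traces through one vectorised Welch call
    shapes = {(t.fps, t.n_frames) for t in present}
    if len(shapes) == 1:
        fps = present[0].fps
        stacked = np.stack([t.values for t in present])
        freqs, psd = _welch_matrix(stacked, fps, cfg)
        energies = bin_bands(freqs, psd)
        return [
            EPTSpectrum(energies[i], embryo_id=t.embryo_id, clip_time=t.clip_time)
            for i, t in enumerate(present)
        ]
    return [compute_spectrum(t, cfg) for t in present]


class BandEnergyExtractor(TransformerMixin, BaseEstimator):
    """Transform raw brightness traces into 60-band EPT energy vectors.

    A scikit-learn transformer: rows of X are equal-length traces sampled
    at ``fps``; ``transform`` returns the (n_traces, 60) band-energy
    matrix. Composable with sklearn pipelines (e.g. followed by
    :class:`eptools.ordination.LogSpectraPCA`).

    Parameters
    ----------
    fps : float
        Sampling rate of the traces, Hz.
    segment_length : int or None
        Welch segment length in frames; None means 10 s of frames.
    overlap_fraction : float
        Fractional overlap between segments, in [0, 1).
    taper : str
        Window function label understood by scipy (e.g. "boxcar", "hann").
    detrend : str
        Per-segment detrending: "none", "constant" or "linear".
    """

    def __init__(
        self,
        fps: float = 30.0,
        segment_length: int | None = None,
        overlap_fraction: float = 0.5,
        taper: str = "boxcar",
        detrend: str = "linear",
    ):
        self.fps = fps
        self.segment_length = segment_length
        self.overlap_fraction = overlap_fraction
        self.taper = taper
        self.detrend = detrend

    def _config(self) -> WelchConfig:
        return WelchConfig(
            segment_length=self.segment_length,
            overlap_fraction=self.overlap_fraction,
            taper=self.taper,
            detrend=self.detrend,
        )

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        cfg = self._config()
        nperseg = cfg.resolve_nperseg(self.fps)
        if X.shape[1] < nperseg:
            raise ValueError(f"traces shorter than one Welch segment ({nperseg} frames)")
        if self.fps < 2 * FMAX_HZ:
            raise ValueError(f"fps must be >= {2 * FMAX_HZ} to cover the analysis range")
        self.n_features_in_ = X.shape[1]
        self.nperseg_ = nperseg
        self.freqs_ = np.arange(nperseg // 2 + 1) * self.fps / nperseg
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "nperseg_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("trace length differs from the fitted length")
        freqs, psd = _welch_matrix(X, self.fps, self._config())
        return bin_bands(freqs, psd)
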