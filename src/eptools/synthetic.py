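"""Synthetic embryo generator.

Emulates the statistical structure of dark-field video of developing
freshwater gastropod embryos: a per-embryo itinerary of physiological
event onsets (ciliary rotation, heartbeat, muscular crawling, radula
function, hatch), band-limited luminance fluctuations that switch on at
those onsets, and optionally full frame stacks with a bright textured
embryo on a dark background.

Two fidelity levels are provided. The trace level produces the
mean-brightness series directly (fast; used for statistics); the frame
level renders each trace into an 8-bit image stack (used to exercise
segmentation).

Temperature treatments are modelled by :class:`TemperatureEffect`:
a multiplicative acceleration of event times (with optional per-event
overrides), amplitude scaling of the physiological signal components
(globally or per component) and an additive shift of their centre
frequencies.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import BrightnessTrace, ClipStack

logger = logging.getLogger(__name__)

__all__ = [
    "EVENT_NAMES",
    "FMAX_HZ",
    "SignalComponent",
    "DevItinerary",
    "TemperatureEffect",
    "NoiseModel",
    "Acquisition",
    "EllipseGeometry",
    "SyntheticEmbryo",
    "SPECIES_PRESETS",
    "default_components",
    "make_itinerary",
    "synth_trace",
    "synth_clip",
    "synth_cohort",
    "events_table",
    "metadata_table",
]

#: the four manually scored physiological onsets, in lymnaeid order
EVENT_NAMES = ("rotation", "heart", "crawling", "radula")

#: upper edge of the analysed temporal-frequency range
FMAX_HZ = 6.0

#: minimum sampling rate so that the analysed range sits below Nyquist
MIN_FPS = 2.0 * FMAX_HZ


def _as_seed(rng_seed):
    """Accept an int, SeedSequence or Generator and return a Generator."""
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


@dataclass(frozen=True)
class SignalComponent:
    """One band-limited physiological signal.

    ``amplitude`` is the peak amplitude for a sinusoid (variance A^2/2)
    and the RMS amplitude for band-limited noise and pulse trains
    (variance A^2); the distinction keeps each waveform's power analytic.
    """

    name: str
    center_freq: float  # Hz
    bandwidth: float  # Hz (full width)
    amplitude: float  # grey levels
    onset_event: str  # event name in EVENT_NAMES, or "4cell"
    waveform: str  # "sinusoid" | "bandnoise" | "pulse"
    pulse_width: float = 0.06  # s, Gaussian sigma of each pulse

    def __post_init__(self) -> None:
        if self.center_freq - self.bandwidth / 2 < 0:
            raise ValueError(f"{self.name}: band extends below 0 Hz")
        if self.center_freq + self.bandwidth / 2 > FMAX_HZ:
            raise ValueError(f"{self.name}: band extends above {FMAX_HZ} Hz")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.waveform not in ("sinusoid", "bandnoise", "pulse"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.onset_event != "4cell" and self.onset_event not in EVENT_NAMES:
            raise ValueError(f"unknown onset event {self.onset_event!r}")


@dataclass(frozen=True)
class DevItinerary:
    """Event times of one embryo, hours post-4-cell (the 4-cell stage is t=0)."""

    rotation: float
    heart: float
    crawling: float
    radula: float
    hatch: float

    def __post_init__(self) -> None:
        if not self.hatch > 0:
            raise ValueError("hatch must be positive")
        for name in EVENT_NAMES:
            t = getattr(self, name)
            if not 0 < t < self.hatch:
                raise ValueError(f"event {name} at {t} h outside (0, hatch)")

    def onset(self, event: str) -> float:
        if event == "4cell":
            return 0.0
        return float(getattr(self, event))

    @property
    def event_times(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in EVENT_NAMES}

    @property
    def order(self) -> tuple[str, ...]:
        """Event names sorted by this embryo's own onset times."""
        return tuple(sorted(EVENT_NAMES, key=self.onset))


@dataclass(frozen=True)
class TemperatureEffect:
    """Treatment effect of a rearing temperature relative to the control.

    timing_factor < 1 accelerates development; ``event_timing`` holds
    per-event multipliers that override the global factor (keys are
    event names or "hatch"); ``amplitude_factor`` scales every signal
    component; ``component_amplitude`` holds per-component overrides
    multiplied on top of it; ``freq_shift`` is added to every component
    centre frequency.
    """

    timing_factor: float = 1.0
    event_timing: dict = field(default_factory=dict)
    amplitude_factor: float = 1.0
    component_amplitude: dict = field(default_factory=dict)
    freq_shift: float = 0.0

    def __post_init__(self) -> None:
        if not self.timing_factor > 0:
            raise ValueError("timing_factor must be positive")
        if self.amplitude_factor < 0:
            raise ValueError("amplitude_factor must be non-negative")

    def transform_components(
        self, components: list[SignalComponent]
    ) -> list[SignalComponent]:
        out = []
        for c in components:
            amp = c.amplitude * self.amplitude_factor * self.component_amplitude.get(c.name, 1.0)
            out.append(replace(c, amplitude=amp, center_freq=c.center_freq + self.freq_shift))
        return out


IDENTITY_EFFECT = TemperatureEffect()


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise and illumination drift added to every trace."""

    baseline: float = 100.0  # grey levels
    white_sigma: float = 1.0  # grey levels
    drift_amplitude: float = 2.0  # grey levels, sub-0.1-Hz slow drift
    drift_freq: float = 0.02  # Hz

    def __post_init__(self) -> None:
        if not self.baseline > 0:
            raise ValueError("baseline must be positive")
        if self.white_sigma < 0 or self.drift_amplitude < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not 0 < self.drift_freq < 0.1:
            raise ValueError("drift must stay below the first 0.1-Hz band")


@dataclass(frozen=True)
class Acquisition:
    """Imaging schedule: clip rate, clip length and inter-clip interval."""

    fps: float = 30.0
    duration: float = 30.0  # s per clip
    interval_h: float = 1.0  # hours between clips

    def __post_init__(self) -> None:
        if self.fps < MIN_FPS:
            raise ValueError(f"fps must be >= {MIN_FPS} so the analysed range is below Nyquist")
        if not (self.duration > 0 and self.interval_h > 0):
            raise ValueError("duration and interval must be positive")


@dataclass(frozen=True)
class EllipseGeometry:
    """Axis-aligned elliptical embryo footprint inside the frame."""

    center_row: float = 32.0
    center_col: float = 32.0
    radius_row: float = 18.0
    radius_col: float = 12.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        return ((rr - self.center_row) / self.radius_row) ** 2 + (
            (cc - self.center_col) / self.radius_col
        ) ** 2 <= 1.0

    def bbox(self, shape: tuple[int, int]):
        from .containers import BoundingBox

        m = self.mask(shape)
        if not m.any():
            raise ValueError("ellipse does not cover any pixel")
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        return BoundingBox(int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)

    def fits(self, shape: tuple[int, int]) -> bool:
        return (
            self.center_row - self.radius_row >= 0
            and self.center_col - self.radius_col >= 0
            and self.center_row + self.radius_row <= shape[0] - 1
            and self.center_col + self.radius_col <= shape[1] - 1
        )


# Species presets. Event times in hours post-4-cell at the control
# temperature; the physid preset places muscular crawling before the
# first heartbeat (the heterochronic order of Physidae), the lymnaeid
# preset the reverse (Lymnaeidae develop cardiovascular function during
# the free-swimming stage, before capsule-wall attachment).
SPECIES_PRESETS: dict[str, DevItinerary] = {
    "lymnaeid": DevItinerary(rotation=40.0, heart=110.0, crawling=150.0, radula=190.0, hatch=240.0),
    "physid": DevItinerary(rotation=30.0, crawling=70.0, heart=95.0, radula=120.0, hatch=160.0),
}


def default_components() -> list[SignalComponent]:
    """Default physiological signal set.

    Frequencies sit inside the ranges attributable to observable
    physiology: ciliary rotation and body flexing / mantle-muscle
    activity occupy the sub-1-Hz bands, heartbeat the ~2-Hz band and
    radula rasping a pulse train at 2.3 Hz. Amplitudes are free
    parameters of the generator (grey levels).
    """
    return [
        SignalComponent("rotation", 0.3, 0.4, 2.0, "rotation", "bandnoise"),
        SignalComponent("crawling", 0.7, 0.6, 2.0, "crawling", "bandnoise"),
        SignalComponent("heart", 2.0, 0.0, 3.0, "heart", "sinusoid"),
        SignalComponent("radula", 2.3, 0.0, 1.5, "radula", "pulse"),
    ]


def make_itinerary(
    species_preset: str,
    temperature_effect: TemperatureEffect | None = None,
    rng_seed=0,
    jitter_sigma: float = 0.05,
) -> DevItinerary:
    """Draw one embryo's event itinerary from a species preset.

    Event times are scaled by the treatment's timing factor (with
    per-event overrides), then jittered. Jitter is applied to the
    *increments* between consecutive events (multiplicative lognormal
    with median 1), which keeps all times positive and can never reorder
    events relative to the preset's ordering.
    """
    effect = temperature_effect or IDENTITY_EFFECT
    try:
        preset = SPECIES_PRESETS[species_preset]
    except KeyError:
        raise ValueError(f"unknown species preset {species_preset!r}") from None

    times = {
        name: preset.onset(name) * effect.event_timing.get(name, effect.timing_factor)
        for name in EVENT_NAMES
    }
    hatch = preset.hatch * effect.event_timing.get("hatch", effect.timing_factor)
    bad = [n for n, t in times.items() if not 0 < t < hatch]
    if bad:
        raise ValueError(f"temperature effect pushes event(s) {bad} outside (0, hatch)")

    order = sorted(EVENT_NAMES, key=times.get)
    seq = np.array([times[name] for name in order] + [hatch])
    if jitter_sigma > 0:
        rng = _as_seed(rng_seed)
        inc = np.diff(np.concatenate([[0.0], seq]))
        inc = inc * rng.lognormal(mean=0.0, sigma=jitter_sigma, size=inc.size)
        seq = np.cumsum(inc)
    jittered = dict(zip(order, seq[:-1]))
    return DevItinerary(hatch=float(seq[-1]), **{k: float(v) for k, v in jittered.items()})


def _waveform(component: SignalComponent, t: np.ndarray, fps: float, rng) -> np.ndarray:
    """Unit-scale waveform; consumes rng draws regardless of later use."""
    n = t.size
    if component.waveform == "sinusoid":
        phase = rng.uniform(0.0, 2.0 * math.pi)
        return np.sin(2.0 * math.pi * component.center_freq * t + phase)
    if component.waveform == "bandnoise":
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fps)
        lo = component.center_freq - component.bandwidth / 2
        hi = component.center_freq + component.bandwidth / 2
        spec[(freqs < lo) | (freqs > hi)] = 0.0
        y = np.fft.irfft(spec, n)
        rms = np.sqrt(np.mean(y**2))
        return y / rms if rms > 0 else y
    # pulse train: periodic Gaussian pulses at the centre frequency with a
    # random phase offset, zero-meaned and normalised to unit RMS
    u = rng.uniform()
    period = 1.0 / component.center_freq
    d = np.mod(t - u * period + period / 2, period) - period / 2
    y = np.exp(-(d**2) / (2.0 * component.pulse_width**2))
    y = y - y.mean()
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def synth_trace(
    itinerary: DevItinerary,
    components: list[SignalComponent],
    noise: NoiseModel,
    clip_time: float,
    fps: float = 30.0,
    duration: float = 30.0,
    rng_seed=0,
    embryo_id: str = "",
) -> BrightnessTrace:
    """Synthesise one clip's mean-brightness trace.

    The trace is baseline + slow drift + the sum of the components whose
    onset event has occurred by ``clip_time`` + white noise. Random draws
    are consumed for *every* component (active or not) in list order, so
    cohorts sharing seeds differ only through the treatment effect.
    """
    if fps < MIN_FPS:
        raise ValueError(f"fps must be >= {MIN_FPS} so the analysed range is below Nyquist")
    n = int(round(fps * duration))
    if n < 2:
        raise ValueError("clip too short")
    rng = _as_seed(rng_seed)
    t = np.arange(n) / fps

    drift_phase = rng.uniform(0.0, 2.0 * math.pi)
    values = noise.baseline + noise.drift_amplitude * np.sin(
        2.0 * math.pi * noise.drift_freq * t + drift_phase
    )
    for comp in components:
        wave = _waveform(comp, t, fps, rng)  # draw even when inactive
        if comp.amplitude > 0 and clip_time >= itinerary.onset(comp.onset_event):
            values = values + comp.amplitude * wave
    if noise.white_sigma > 0:
        values = values + noise.white_sigma * rng.standard_normal(n)
    else:
        rng.standard_normal(n)  # keep draw order identical across noise settings
    return BrightnessTrace(values, fps=fps, clip_time=clip_time, embryo_id=embryo_id)


def _synth_traces_batch(
    itinerary: DevItinerary,
    components: list[SignalComponent],
    noise: NoiseModel,
    clip_times: np.ndarray,
    fps: float,
    duration: float,
    seeds: list,
    embryo_id: str,
) -> list[BrightnessTrace]:
    """Vectorised equivalent of calling :func:`synth_trace` per clip.

    Random draws are taken clip by clip in exactly the order synth_trace
    takes them; only the deterministic filtering/accumulation is batched,
    so the output is bit-identical to the per-clip path.
    """
    n = int(round(fps * duration))
    n_clips = len(clip_times)
    t = np.arange(n) / fps
    drift_phase = np.empty(n_clips)
    white = np.empty((n_clips, n))
    comp_scalar = {c.name: np.empty(n_clips) for c in components}
    comp_white = {
        c.name: np.empty((n_clips, n)) for c in components if c.waveform == "bandnoise"
    }
    for i, seed in enumerate(seeds):
        rng = _as_seed(seed)
        drift_phase[i] = rng.uniform(0.0, 2.0 * math.pi)
        for c in components:
            if c.waveform == "sinusoid":
                comp_scalar[c.name][i] = rng.uniform(0.0, 2.0 * math.pi)
            elif c.waveform == "bandnoise":
                comp_white[c.name][i] = rng.standard_normal(n)
            else:
                comp_scalar[c.name][i] = rng.uniform()
        white[i] = rng.standard_normal(n)

    values = noise.baseline + noise.drift_amplitude * np.sin(
        2.0 * math.pi * noise.drift_freq * t[None, :] + drift_phase[:, None]
    )
    active = {
        c.name: clip_times >= itinerary.onset(c.onset_event) for c in components
    }
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    for c in components:
        if c.waveform == "sinusoid":
            wave = np.sin(
                2.0 * math.pi * c.center_freq * t[None, :] + comp_scalar[c.name][:, None]
            )
        elif c.waveform == "bandnoise":
            spec = np.fft.rfft(comp_white[c.name], axis=-1)
            lo = c.center_freq - c.bandwidth / 2
            hi = c.center_freq + c.bandwidth / 2
            spec[:, (freqs < lo) | (freqs > hi)] = 0.0
            wave = np.fft.irfft(spec, n, axis=-1)
            rms = np.sqrt(np.mean(wave**2, axis=-1, keepdims=True))
            rms[rms == 0] = 1.0
            wave = wave / rms
        else:
            period = 1.0 / c.center_freq
            d = (
                np.mod(t[None, :] - comp_scalar[c.name][:, None] * period + period / 2, period)
                - period / 2
            )
            wave = np.exp(-(d**2) / (2.0 * c.pulse_width**2))
            wave = wave - wave.mean(axis=-1, keepdims=True)
            rms = np.sqrt(np.mean(wave**2, axis=-1, keepdims=True))
            rms[rms == 0] = 1.0
            wave = wave / rms
        if c.amplitude > 0:
            gate = active[c.name].astype(float) * c.amplitude
            values = values + gate[:, None] * wave
    if noise.white_sigma > 0:
        values = values + noise.white_sigma * white
    return [
        BrightnessTrace(values[i], fps=fps, clip_time=float(ct), embryo_id=embryo_id)
        for i, ct in enumerate(clip_times)
    ]


def synth_clip(
    trace: BrightnessTrace,
    frame_size: tuple[int, int] = (64, 64),
    geometry: EllipseGeometry | None = None,
    rng_seed=0,
) -> ClipStack:
    """Render a brightness trace into an 8-bit dark-field frame stack.

    Each frame holds a bright, statically textured ellipse on a zero
    background. Texture weights are normalised so that the mean pixel
    value inside the ellipse's true bounding box equals the trace value
    for that frame to within quantisation error (< 1 grey level).
    """
    geometry = geometry or EllipseGeometry(
        center_row=frame_size[0] / 2.0,
        center_col=frame_size[1] / 2.0,
        radius_row=frame_size[0] * 0.28,
        radius_col=frame_size[1] * 0.19,
    )
    if not geometry.fits(frame_size):
        raise ValueError("ellipse does not fit inside the frame")
    mask = geometry.mask(frame_size)
    box = geometry.bbox(frame_size)
    rng = _as_seed(rng_seed)

    weights = np.zeros(frame_size)
    weights[mask] = rng.uniform(0.5, 1.5, size=int(mask.sum()))
    sub = weights[box.slices]
    weights *= sub.size / sub.sum()  # mean weight over the true bbox == 1

    stack = trace.values[:, None, None] * weights[None, :, :]
    if stack.max() > 255.0:
        raise ValueError(
            "trace brightness too high for 8-bit rendering; lower the baseline or amplitudes"
        )
    frames = np.rint(stack).astype(np.uint8)
    return ClipStack(frames, fps=trace.fps, clip_time=trace.clip_time, embryo_id=trace.embryo_id)


@dataclass
class SyntheticEmbryo:
    """One synthetic embryo: itinerary, hourly traces and metadata."""

    embryo_id: str
    species_preset: str
    temperature_label: str
    itinerary: DevItinerary
    acquisition: Acquisition
    traces: list
    clips: list | None = None

    @property
    def events(self) -> dict[str, float]:
        ev = self.itinerary.event_times
        ev["hatch"] = self.itinerary.hatch
        return ev


def synth_cohort(
    n_embryos: int,
    preset: str,
    temperature_effect: TemperatureEffect | None = None,
    acquisition: Acquisition | None = None,
    rng_seed=0,
    components: list[SignalComponent] | None = None,
    noise: NoiseModel | None = None,
    jitter_sigma: float = 0.05,
    temperature_label: str = "20C",
    fidelity: str = "trace",
    frame_size: tuple[int, int] = (64, 64),
    geometry: EllipseGeometry | None = None,
    id_prefix: str | None = None,
) -> list[SyntheticEmbryo]:
    """Generate a cohort of embryos under one temperature treatment.

    Clips are taken from t=0 up to each embryo's hatch at the acquisition
    interval (``floor(hatch/interval) + 1`` clips). All randomness derives
    deterministically from the master seed through a SeedSequence tree, so
    the cohort is bit-reproducible and two cohorts sharing a master seed
    differ only through the treatment effect.
    """
    if n_embryos < 2:
        raise ValueError("a cohort needs at least 2 embryos")
    if fidelity not in ("trace", "frames"):
        raise ValueError("fidelity must be 'trace' or 'frames'")
    effect = temperature_effect or IDENTITY_EFFECT
    acquisition = acquisition or Acquisition()
    noise = noise or NoiseModel()
    base_components = components if components is not None else default_components()
    effective = effect.transform_components(base_components)
    prefix = id_prefix if id_prefix is not None else f"{temperature_label}_"

    master = np.random.SeedSequence(rng_seed) if not isinstance(rng_seed, np.random.SeedSequence) else rng_seed
    cohort = []
    for i, emb_ss in enumerate(master.spawn(n_embryos)):
        it_ss, trace_ss, tex_ss = emb_ss.spawn(3)
        itin = make_itinerary(preset, effect, it_ss, jitter_sigma=jitter_sigma)
        n_clips = int(math.floor(itin.hatch / acquisition.interval_h)) + 1
        clip_times = np.arange(n_clips) * acquisition.interval_h
        embryo_id = f"{prefix}{i:03d}"
        traces = _synth_traces_batch(
            itin,
            effective,
            noise,
            clip_times,
            fps=acquisition.fps,
            duration=acquisition.duration,
            seeds=trace_ss.spawn(n_clips),
            embryo_id=embryo_id,
        )
        clips = None
        if fidelity == "frames":
            clips = [
                synth_clip(tr, frame_size=frame_size, geometry=geometry, rng_seed=c_ss)
                for tr, c_ss in zip(traces, tex_ss.spawn(n_clips))
            ]
        cohort.append(
            SyntheticEmbryo(
                embryo_id=embryo_id,
                species_preset=preset,
                temperature_label=temperature_label,
                itinerary=itin,
                acquisition=acquisition,
                traces=traces,
                clips=clips,
            )
        )
    return cohort


def events_table(cohort: list[SyntheticEmbryo]):
    """Long-format developmental event table (embryo_id, event, time_h)."""
    import pandas as pd

    rows = [
        {"embryo_id": emb.embryo_id, "event": event, "time_h": time}
        for emb in cohort
        for event, time in emb.events.items()
    ]
    return pd.DataFrame(rows, columns=["embryo_id", "event", "time_h"])


def metadata_table(cohort: list[SyntheticEmbryo]):
    """Cohort metadata (embryo_id, species_preset, temperature_label, fps, clip_interval_h)."""
    import pandas as pd

    rows = [
        {
            "embryo_id": emb.embryo_id,
            "species_preset": emb.species_preset,
            "temperature_label": emb.temperature_label,
            "fps": emb.acquisition.fps,
            "clip_interval_h": emb.acquisition.interval_h,
        }
        for emb in cohort
    ]
    return pd.DataFrame(
        rows, columns=["embryo_id", "species_preset", "temperature_label", "fps", "clip_interval_h"]
    )
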