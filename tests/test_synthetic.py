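"""Generator contracts: itineraries, traces, clips and cohorts."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eptools.containers import BoundingBox
from eptools.synthetic import (
    Acquisition,
    EllipseGeometry,
    NoiseModel,
    SPECIES_PRESETS,
    SignalComponent,
    TemperatureEffect,
    default_components,
    make_itinerary,
    synth_clip,
    synth_cohort,
    synth_trace,
)
from conftest import QUIET, sinusoid_trace


class TestMakeItinerary:
    def test_identity_effect_no_jitter_returns_preset(self):
        it = make_itinerary("lymnaeid", TemperatureEffect(), jitter_sigma=0.0)
        preset = SPECIES_PRESETS["lymnaeid"]
        for name in ("rotation", "heart", "crawling", "radula", "hatch"):
            assert getattr(it, name) == getattr(preset, name)

    def test_timing_factor_scales_event_times(self):
        it = make_itinerary("lymnaeid", TemperatureEffect(timing_factor=0.8), jitter_sigma=0.0)
        assert it.heart == pytest.approx(0.8 * 110.0)
        assert it.hatch == pytest.approx(0.8 * 240.0)

    def test_per_event_override_beats_global_factor(self):
        eff = TemperatureEffect(timing_factor=0.8, event_timing={"rotation": 1.0})
        it = make_itinerary("lymnaeid", eff, jitter_sigma=0.0)
        assert it.rotation == pytest.approx(40.0)
        assert it.heart == pytest.approx(88.0)

    @pytest.mark.parametrize(
        "preset,earlier,later",
        [("lymnaeid", "heart", "crawling"), ("physid", "crawling", "heart")],
    )
    @pytest.mark.parametrize("seed", range(5))
    def test_heterochronic_order_per_preset(self, preset, earlier, later, seed):
        it = make_itinerary(preset, rng_seed=seed)
        assert getattr(it, earlier) < getattr(it, later)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown species preset"):
            make_itinerary("nonexistent")

    def test_effect_pushing_event_past_hatch_rejected(self):
        eff = TemperatureEffect(event_timing={"radula": 2.0, "hatch": 0.5})
        with pytest.raises(ValueError, match="outside"):
            make_itinerary("lymnaeid", eff, jitter_sigma=0.0)

    @given(seed=st.integers(0, 2**31 - 1), sigma=st.floats(0.01, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_jitter_never_reorders_events(self, seed, sigma):
        it = make_itinerary("physid", rng_seed=seed, jitter_sigma=sigma)
        assert it.order == SPECIES_PRESETS["physid"].order
        assert 0 < min(it.event_times.values()) and max(it.event_times.values()) < it.hatch


class TestSynthTrace:
    def test_before_all_onsets_is_constant_baseline(self, lymnaeid_itinerary):
        tr = synth_trace(
            lymnaeid_itinerary, default_components(), QUIET, clip_time=1.0, rng_seed=0
        )
        assert np.allclose(tr.values, 100.0)

    def test_active_sinusoid_variance_is_half_amplitude_squared(self):
        tr = sinusoid_trace(amplitude=3.0)
        assert tr.values.var() == pytest.approx(4.5, rel=1e-9)

    def test_same_seed_same_trace(self, lymnaeid_itinerary):
        kwargs = dict(clip_time=200.0, fps=30.0, duration=30.0, rng_seed=42)
        a = synth_trace(lymnaeid_itinerary, default_components(), NoiseModel(), **kwargs)
        b = synth_trace(lymnaeid_itinerary, default_components(), NoiseModel(), **kwargs)
        assert np.array_equal(a.values, b.values)

    def test_sub_nyquist_fps_rejected(self, lymnaeid_itinerary):
        with pytest.raises(ValueError, match="Nyquist"):
            synth_trace(lymnaeid_itinerary, [], QUIET, clip_time=0.0, fps=10.0)

    def test_empty_component_list_gives_noise_only_trace(self, lymnaeid_itinerary):
        tr = synth_trace(
            lymnaeid_itinerary, [], NoiseModel(white_sigma=1.0, drift_amplitude=0.0),
            clip_time=0.0, rng_seed=3,
        )
        assert tr.values.std() > 0

    def test_component_band_edges_validated(self):
        with pytest.raises(ValueError, match="below 0"):
            SignalComponent("x", 0.1, 0.4, 1.0, "heart", "bandnoise")
        with pytest.raises(ValueError, match="above"):
            SignalComponent("x", 5.9, 0.4, 1.0, "heart", "bandnoise")


class TestSynthClip:
    def test_constant_trace_gives_identical_frames(self, lymnaeid_itinerary):
        tr = synth_trace(lymnaeid_itinerary, [], QUIET, clip_time=0.0, duration=1.0)
        clip = synth_clip(tr, rng_seed=1)
        assert np.array_equal(clip.frames[0], clip.frames[-1])
        means = clip.frames.mean(axis=(1, 2))
        assert np.ptp(means) == 0

    def test_bbox_mean_recovers_trace_within_one_grey_level(self):
        tr = sinusoid_trace(amplitude=3.0, duration=10.0)
        geometry = EllipseGeometry(32, 32, 18, 12)
        clip = synth_clip(tr, frame_size=(64, 64), geometry=geometry, rng_seed=2)
        box = geometry.bbox((64, 64))
        recovered = clip.frames[:, box.slices[0], box.slices[1]].mean(axis=(1, 2))
        assert np.max(np.abs(recovered - tr.values)) <= 1.0

    def test_background_much_darker_than_embryo(self):
        tr = sinusoid_trace(duration=1.0)
        clip = synth_clip(tr, frame_size=(64, 64), rng_seed=0)
        geometry = EllipseGeometry(32, 32, 64 * 0.28, 64 * 0.19)
        mask = geometry.mask((64, 64))
        assert clip.frames[0][~mask].mean() < 0.05 * clip.frames[0][mask].mean()

    def test_ellipse_outside_frame_rejected(self):
        tr = sinusoid_trace(duration=1.0)
        with pytest.raises(ValueError, match="fit"):
            synth_clip(tr, frame_size=(32, 32), geometry=EllipseGeometry(16, 16, 20, 10))


class TestSynthCohort:
    def test_cohort_is_bit_reproducible(self):
        kwargs = dict(n_embryos=2, preset="physid", rng_seed=9,
                      acquisition=Acquisition(interval_h=40.0))
        a, b = synth_cohort(**kwargs), synth_cohort(**kwargs)
        for ea, eb in zip(a, b):
            assert ea.itinerary == eb.itinerary
            for ta, tb in zip(ea.traces, eb.traces):
                assert np.array_equal(ta.values, tb.values)

    def test_clip_count_is_floor_hatch_plus_one(self):
        cohort = synth_cohort(3, "physid", rng_seed=4)
        for emb in cohort:
            assert len(emb.traces) == int(np.floor(emb.itinerary.hatch)) + 1

    def test_amplitude_effect_changes_only_component_amplitude(self):
        base = dict(n_embryos=2, preset="physid", rng_seed=11, jitter_sigma=0.0,
                    acquisition=Acquisition(interval_h=40.0),
                    noise=NoiseModel(white_sigma=0.0, drift_amplitude=0.0))
        plain = synth_cohort(temperature_effect=TemperatureEffect(), **base)
        boosted = synth_cohort(temperature_effect=TemperatureEffect(amplitude_factor=1.5), **base)
        for ep, eb in zip(plain, boosted):
            for tp, tb in zip(ep.traces, eb.traces):
                fluct_p = tp.values - 100.0
                fluct_b = tb.values - 100.0
                assert np.allclose(fluct_b, 1.5 * fluct_p, atol=1e-9)

    def test_single_embryo_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            synth_cohort(1, "physid")
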