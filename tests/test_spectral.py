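"""Welch decomposition, 0.1-Hz band binning and total energy."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eptools.containers import BrightnessTrace
from eptools.spectral import (
    BAND_WIDTH_HZ,
    FMAX_HZ,
    N_BANDS,
    BandEnergyExtractor,
    WelchConfig,
    bin_bands,
    compute_spectrum,
    spectra_for_embryo,
    total_energy,
    welch_psd,
)
from eptools.synthetic import NoiseModel, SignalComponent, make_itinerary, synth_trace
from conftest import QUIET, sinusoid_trace


def quadrature_oracle(freqs, psd):
    """Direct rectangle-rule integral of the DC-excluded PSD below 6 Hz."""
    df = freqs[1] - freqs[0]
    keep = (freqs > 0) & (np.floor(freqs / BAND_WIDTH_HZ + 1e-6) < N_BANDS)
    return float((psd[keep] * df).sum())


class TestWelchPsd:
    def test_constant_trace_has_zero_psd(self):
        tr = BrightnessTrace(np.full(900, 42.0), fps=30.0)
        _, psd = welch_psd(tr, WelchConfig(detrend="constant"))
        assert np.allclose(psd, 0.0)

    def test_white_noise_integral_matches_variance(self):
        """Parseval: the integrated PSD estimates the sample variance."""
        rng = np.random.default_rng(0)
        cfg = WelchConfig(detrend="none")
        integrals, variances = [], []
        for _ in range(20):
            x = rng.standard_normal(900) * 2.0
            tr = BrightnessTrace(x, fps=30.0)
            freqs, psd = welch_psd(tr, cfg)
            df = freqs[1] - freqs[0]
            integrals.append((psd * df).sum())
            variances.append(x.var())
        assert np.mean(integrals) == pytest.approx(np.mean(variances), rel=0.05)

    def test_sinusoid_peak_location_and_power(self):
        tr = sinusoid_trace(amplitude=2.5, freq=2.0, fps=30.0, duration=30.0)
        freqs, psd = welch_psd(tr)
        assert 1.95 <= freqs[np.argmax(psd)] <= 2.05
        df = freqs[1] - freqs[0]
        peak = np.abs(freqs - 2.0) <= 0.15
        assert (psd[peak] * df).sum() == pytest.approx(2.5**2 / 2, rel=0.05)
        # independent oracle: raw periodogram of the full trace
        raw = np.abs(np.fft.rfft(tr.values - tr.values.mean())) ** 2 / tr.values.size**2 * 2
        raw_freqs = np.fft.rfftfreq(tr.values.size, 1 / 30.0)
        assert raw_freqs[np.argmax(raw)] == pytest.approx(2.0, abs=0.05)

    def test_short_trace_rejected(self):
        tr = BrightnessTrace(np.ones(100), fps=30.0)
        with pytest.raises(ValueError, match="too short"):
            welch_psd(tr)


class TestBinBands:
    def test_exactly_sixty_bands(self):
        spec = compute_spectrum(sinusoid_trace())
        assert spec.band_energy.shape == (N_BANDS,) == (60,)

    def test_point_mass_at_band_edge_goes_to_upper_band(self):
        freqs = np.arange(0, 151) * 0.1  # 0..15 Hz at 0.1 Hz
        psd = np.zeros_like(freqs)
        psd[20] = 5.0  # mass at exactly 2.0 Hz
        bands = bin_bands(freqs, psd)
        assert bands[20] == pytest.approx(5.0 * 0.1)
        assert np.count_nonzero(bands) == 1

    def test_dc_is_excluded(self):
        freqs = np.arange(0, 151) * 0.1
        psd = np.zeros_like(freqs)
        psd[0] = 100.0
        assert bin_bands(freqs, psd).sum() == 0.0

    def test_nyquist_below_six_hz_rejected(self):
        freqs = np.linspace(0, 5.0, 51)
        with pytest.raises(ValueError, match="Nyquist"):
            bin_bands(freqs, np.ones_like(freqs))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_conservation_against_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tr = BrightnessTrace(100 + rng.standard_normal(900) * rng.uniform(0.5, 5), fps=30.0)
        freqs, psd = welch_psd(tr)
        spec = compute_spectrum(tr)
        oracle = quadrature_oracle(freqs, psd)
        assert spec.total_energy == pytest.approx(oracle, rel=1e-9)


class TestTotalEnergy:
    def test_trivial_sums(self):
        from eptools.spectral import EPTSpectrum

        assert total_energy(EPTSpectrum(np.zeros(60))) == 0.0
        assert total_energy(EPTSpectrum(np.ones(60))) == 60.0

    def test_doubling_amplitude_quadruples_energy(self):
        e1 = compute_spectrum(sinusoid_trace(amplitude=1.5)).total_energy
        e2 = compute_spectrum(sinusoid_trace(amplitude=3.0)).total_energy
        assert e2 == pytest.approx(4 * e1, rel=1e-6)

    @pytest.mark.parametrize("freq", [0.5, 2.0, 3.7, 5.9])
    def test_pure_tone_localised_in_owning_band(self, freq):
        spec = compute_spectrum(sinusoid_trace(amplitude=2.0, freq=freq))
        band = int(np.floor(freq / BAND_WIDTH_HZ + 1e-6))
        assert spec.band_energy[band] >= 0.9 * spec.total_energy

    def test_mid_band_tone_localised_at_fine_resolution(self):
        """A 2.05-Hz tone with a Hann taper at full-trace resolution stays in band 20."""
        tr = sinusoid_trace(amplitude=2.0, freq=2.05, fps=30.0, duration=30.0)
        cfg = WelchConfig(segment_length=900, taper="hann")
        spec_cfg = compute_spectrum(tr, cfg)
        assert spec_cfg.band_energy[20] >= 0.9 * spec_cfg.total_energy

    def test_band_energy_monotone_in_amplitude(self):
        energies = [
            compute_spectrum(sinusoid_trace(amplitude=a)).band_energy[20]
            for a in (0.0, 1.0, 2.0, 4.0)
        ]
        assert all(b > a for a, b in zip(energies, energies[1:]))


class TestSpectraForEmbryo:
    def _traces(self, times, embryo_id="e1"):
        itin = make_itinerary("lymnaeid", jitter_sigma=0.0)
        from eptools.synthetic import default_components

        return [
            synth_trace(itin, default_components(), QUIET, clip_time=t, rng_seed=i,
                        embryo_id=embryo_id)
            for i, t in enumerate(times)
        ]

    def test_order_preserved_and_missing_skipped(self):
        traces = self._traces([0.0, 50.0, 120.0, 200.0])
        traces.insert(2, None)  # a failed clip
        spectra = spectra_for_embryo(traces)
        assert [s.clip_time for s in spectra] == [0.0, 50.0, 120.0, 200.0]

    def test_duplicate_clip_time_rejected(self):
        traces = self._traces([10.0, 10.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            spectra_for_embryo(traces)

    def test_mixed_embryos_rejected(self):
        traces = self._traces([0.0]) + self._traces([5.0], embryo_id="e2")
        with pytest.raises(ValueError, match="mix"):
            spectra_for_embryo(traces)

    def test_heart_band_rises_after_heart_onset(self):
        spectra = spectra_for_embryo(self._traces([50.0, 200.0]))
        before, after = spectra[0].band_energy[20], spectra[1].band_energy[20]
        assert after > 10 * before

    def test_band_energies_fps_invariant(self):
        """The same continuous signal sampled at 30 and 48 fps yields matching bands."""
        itin = make_itinerary("lymnaeid", jitter_sigma=0.0)
        comps = [
            SignalComponent("heart", 2.0, 0.0, 3.0, "heart", "sinusoid"),
            SignalComponent("radula", 2.3, 0.0, 1.5, "radula", "pulse"),
        ]
        spectra = {}
        for fps in (30.0, 48.0):
            tr = synth_trace(itin, comps, QUIET, clip_time=200.0, fps=fps, rng_seed=5)
            spectra[fps] = compute_spectrum(tr).band_energy
        total = spectra[30.0].sum()
        occupied = np.flatnonzero(spectra[30.0] > 0.01 * total)
        for k in occupied:
            assert spectra[48.0][k] == pytest.approx(spectra[30.0][k], rel=0.10)


class TestBandEnergyExtractor:
    def test_transformer_matches_function_path(self):
        traces = [sinusoid_trace(amplitude=a, seed=s) for a, s in ((1.0, 0), (2.0, 1), (3.0, 2))]
        X = np.stack([t.values for t in traces])
        ext = BandEnergyExtractor(fps=30.0).fit(X)
        out = ext.transform(X)
        expected = np.stack([compute_spectrum(t).band_energy for t in traces])
        assert np.allclose(out, expected)

    def test_sklearn_params_roundtrip(self):
        ext = BandEnergyExtractor(fps=48.0, taper="hann")
        params = ext.get_params()
        clone = BandEnergyExtractor(**params)
        assert clone.get_params() == params
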