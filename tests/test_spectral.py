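"""Power spectra, band powers, aggregation and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aphasia_eeg import (
    BandDefinition,
    DEFAULT_BANDS,
    Recording,
    aggregate,
    band_power,
    make_windows,
    power_spectrum,
)
from aphasia_eeg.spectral import validate_bands
from conftest import direct_dft_power

FS = 128
BAND = {b.name: b for b in DEFAULT_BANDS}


def _tone(f_hz, amp=1.0, seconds=5, fs=FS, phase=0.3):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * f_hz * t + phase)


class TestPowerSpectrum:
    def test_on_bin_tone_power_is_amplitude_squared_over_two(self):
        a = 3.0
        freqs, power = power_spectrum(_tone(10.0, a), FS)
        peak = int(np.argmax(power))
        assert freqs[peak] == pytest.approx(10.0)
        assert power[peak] == pytest.approx(a ** 2 / 2, rel=1e-9)
        assert power.sum() == pytest.approx(a ** 2 / 2, rel=1e-9)

    @pytest.mark.parametrize("n", [64, 127, 640])
    def test_parseval_on_white_noise(self, n):
        x = np.random.default_rng(n).standard_normal(n)
        _, power = power_spectrum(x, FS)
        assert power.sum() == pytest.approx(np.mean(x ** 2), rel=1e-6)

    @pytest.mark.parametrize("n", [16, 63, 128, 640, 1024])
    def test_fft_path_matches_direct_dft_oracle(self, n):
        x = 10 * np.random.default_rng(n + 1).standard_normal(n)
        freqs, power = power_spectrum(x, FS)
        o_freqs, o_power = direct_dft_power(x, FS)
        np.testing.assert_allclose(freqs, o_freqs, rtol=0, atol=1e-9)
        np.testing.assert_allclose(power, o_power,
                                   rtol=1e-8, atol=1e-8 * power.max())

    def test_hann_taper_preserves_broadband_power_approximately(self):
        x = np.random.default_rng(9).standard_normal(640)
        _, power = power_spectrum(x, FS, taper="hann")
        assert power.sum() == pytest.approx(np.mean(x ** 2), rel=0.15)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.array([1.0]), FS)


class TestBandPower:
    def test_pure_alpha_tone_lands_entirely_in_alpha(self):
        freqs, power = power_spectrum(_tone(10.0), FS)
        non_dc = power[1:].sum()
        assert band_power(freqs, power, BAND["Alpha"]) == \
            pytest.approx(non_dc, rel=1e-9)
        for name in ("Delta", "Theta", "BetaL", "BetaH", "Gamma"):
            assert band_power(freqs, power, BAND[name]) < 1e-12 * non_dc

    def test_edge_tone_counts_in_upper_band_half_open_rule(self):
        freqs, power = power_spectrum(_tone(12.0), FS)
        assert band_power(freqs, power, BAND["BetaL"]) > 0.49
        assert band_power(freqs, power, BAND["Alpha"]) == pytest.approx(0.0,
                                                                        abs=1e-12)

    def test_mixture_band_ratio_follows_amplitude_squares(self):
        a1, a2 = 2.0, 5.0
        x = _tone(6.0, a1) + _tone(20.0, a2, phase=1.1)
        freqs, power = power_spectrum(x, FS)
        theta = band_power(freqs, power, BAND["Theta"])
        beta_h = band_power(freqs, power, BAND["BetaH"])
        assert theta / beta_h == pytest.approx(a1 ** 2 / a2 ** 2, rel=1e-6)

    def test_band_above_nyquist_rejected(self):
        freqs, power = power_spectrum(_tone(10.0), FS)
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(freqs, power, BandDefinition("HF", 70.0, 90.0))


class TestValidateBands:
    def test_default_bands_accepted(self):
        validate_bands(DEFAULT_BANDS)

    def test_gap_between_analyzed_bands_rejected(self):
        bad = (BandDefinition("Theta", 4, 8), BandDefinition("Alpha", 9, 12))
        with pytest.raises(ValueError, match="tile"):
            validate_bands(bad)


def _window_set(data, schedule, labels=("F7", "F3", "F4", "F8")):
    data = np.atleast_2d(data)
    rec = Recording(samples=data, fs=FS, channel_labels=labels[:data.shape[0]],
                    task_onset_sample=0)
    return make_windows(rec, schedule)


class TestAggregate:
    def test_single_pure_tone_normalizes_to_one(self, tiny_schedule):
        ws = _window_set(_tone(10.0, 5.0, seconds=40), tiny_schedule,
                         labels=("F3",))
        table = aggregate(ws)
        assert table.normalized.loc["F3", "Alpha"] == pytest.approx(1.0)
        assert table.n_windows_used["F3"] == 8
        # Delta computed in raw form but absent from the normalized display
        assert "Delta" in table.raw_power_uv2.columns
        assert "Delta" not in table.normalized.columns

    def test_mean_over_windows_is_arithmetic(self, tiny_schedule):
        # alternate 6 Hz and 10 Hz tones window by window, amplitude 2
        n_per = 5 * FS
        data = np.concatenate([
            _tone(6.0 if i % 2 == 0 else 10.0, 2.0, seconds=5)
            for i in range(8)
        ])
        ws = _window_set(data, tiny_schedule, labels=("F3",))
        table = aggregate(ws)
        raw = table.raw_power_uv2.loc["F3"]
        assert raw["Theta"] == pytest.approx(1.0, rel=1e-9)
        assert raw["Alpha"] == pytest.approx(1.0, rel=1e-9)
        norm = table.normalized.loc["F3"]
        assert norm["Theta"] == pytest.approx(0.5, rel=1e-9)
        assert norm["Alpha"] == pytest.approx(0.5, rel=1e-9)
        assert norm[["BetaL", "BetaH", "Gamma"]].sum() == pytest.approx(0.0,
                                                                        abs=1e-9)

    def test_normalized_rows_live_on_the_simplex(self, tiny_schedule):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((4, 40 * FS)) * 10
        table = aggregate(_window_set(data, tiny_schedule))
        sums = table.normalized.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert (table.normalized.values >= 0).all()

    def test_zero_accepted_windows_names_electrode(self, tiny_schedule):
        ws = _window_set(np.random.default_rng(1).standard_normal((1, 40 * FS)),
                         tiny_schedule, labels=("F3",))
        with pytest.raises(ValueError, match="F3"):
            aggregate(ws, include_labels=frozenset({"no_such_label"}))

    @given(scale=st.floats(0.1, 100.0))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_scale_invariance_of_normalized_profile(self, scale):
        from aphasia_eeg import build_schedule
        schedule = build_schedule(5, 2, 40, [])
        rng = np.random.default_rng(42)
        data = rng.standard_normal((1, 40 * FS)) * 10
        base = aggregate(_window_set(data, schedule, labels=("F3",)))
        scaled = aggregate(_window_set(data * scale, schedule, labels=("F3",)))
        np.testing.assert_allclose(scaled.normalized.values,
                                   base.normalized.values, atol=1e-9)
        np.testing.assert_allclose(
            scaled.raw_power_uv2.values,
            base.raw_power_uv2.values * scale ** 2, rtol=1e-9)

    def test_tsv_export_round_trips_values(self, tiny_schedule, tmp_path):
        rng = np.random.default_rng(8)
        table = aggregate(_window_set(rng.standard_normal((4, 40 * FS)),
                                      tiny_schedule))
        path = table.to_tsv(tmp_path / "bp.tsv")
        back = pd.read_csv(path, sep="\t")
        assert set(back.columns) == {"electrode", "band", "raw_power_uv2",
                                     "normalized", "n_windows_used"}
        assert len(back) == 4 * 6


class TestRmsSpectrumConsistency:
    def test_window_rms_squared_equals_spectrum_sum(self, tiny_schedule):
        rng = np.random.default_rng(12)
        data = rng.standard_normal(40 * FS) * 15
        ws = _window_set(data, tiny_schedule, labels=("F3",))
        for w in ws.windows:
            seg = ws.window_samples(w)
            _, power = power_spectrum(seg, FS)
            assert power.sum() == pytest.approx(w.rms_uv ** 2, rel=1e-6)
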