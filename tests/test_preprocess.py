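"""DC removal, filtering, windowing, RMS and artifact flagging."""

import dataclasses

import numpy as np
import pytest

from aphasia_eeg import (
    FilterSpec,
    Recording,
    apply_filter,
    flag_artifacts,
    make_windows,
    remove_dc,
)

FS = 128


def _rms(x):
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


class TestRemoveDc:
    def test_constant_maps_to_zero(self):
        np.testing.assert_allclose(remove_dc([7.0, 7, 7, 7]), np.zeros(4))

    def test_zero_mean_signal_is_fixed_point(self):
        x = np.array([1.0, -1, 1, -1])
        np.testing.assert_array_equal(remove_dc(x), x)

    def test_offset_sine_recovers_sine(self):
        t = np.arange(FS * 2) / FS
        sine = 10 * np.sin(2 * np.pi * 10 * t)
        out = remove_dc(sine + 4200.0)
        np.testing.assert_allclose(out, sine, atol=1e-9)
        assert abs(out.mean()) < 1e-9

    def test_matrix_input_demeans_each_channel(self):
        x = np.array([[1.0, 3.0], [10.0, 10.0]])
        out = remove_dc(x)
        np.testing.assert_allclose(out, [[-1, 1], [0, 0]])

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            remove_dc(np.array([]))


class TestApplyFilter:
    def _tone(self, f_hz, seconds=10):
        t = np.arange(int(seconds * FS)) / FS
        return np.sin(2 * np.pi * f_hz * t)

    @pytest.mark.parametrize("family", ["iir", "fir"])
    def test_stopband_tone_attenuated(self, family):
        # steady-state response: drop 2 s at each edge so filtfilt
        # start-up transients do not dominate the stopband measurement
        spec = FilterSpec(family=family,
                          order=6 if family == "iir" else 256)
        x = self._tone(50.0)
        y = apply_filter(x, spec, FS)[2 * FS:-2 * FS]
        assert _rms(y) < 0.05 * _rms(x)

    @pytest.mark.parametrize("family", ["iir", "fir"])
    def test_passband_tone_preserved(self, family):
        spec = FilterSpec(family=family,
                          order=6 if family == "iir" else 256)
        x = self._tone(10.0)
        y = apply_filter(x, spec, FS)[2 * FS:-2 * FS]
        assert _rms(y) == pytest.approx(_rms(x), rel=0.05)

    def test_zero_signal_maps_to_zero(self):
        y = apply_filter(np.zeros(FS), FilterSpec(), FS)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_zero_phase_preserves_pulse_peak_position(self):
        x = np.zeros(4 * FS)
        x[2 * FS] = 1.0
        y = apply_filter(x, FilterSpec(zero_phase=True), FS)
        assert abs(int(np.argmax(np.abs(y))) - 2 * FS) <= 1

    def test_output_length_equals_input_length(self):
        x = np.random.default_rng(0).standard_normal(3 * FS)
        assert apply_filter(x, FilterSpec(), FS).shape == x.shape

    def test_cutoff_at_nyquist_rejected(self):
        spec = FilterSpec(cutoffs_hz=(1.0, 64.0))
        with pytest.raises(ValueError, match="cutoff"):
            apply_filter(np.zeros(FS), spec, FS)

    def test_bandpass_needs_increasing_cutoffs(self):
        with pytest.raises(ValueError):
            FilterSpec(cutoffs_hz=(45.0, 1.0))


def _task_recording(data):
    return Recording(samples=np.atleast_2d(data), fs=FS,
                     channel_labels=tuple(f"F{i * 2 + 3}" for i
                                          in range(np.atleast_2d(data).shape[0])),
                     task_onset_sample=0)


class TestMakeWindows:
    def test_published_task_gives_48_windows_per_channel(self, paper_schedule):
        rec = _task_recording(np.zeros(240 * FS))
        ws = make_windows(rec, paper_schedule)
        assert ws.n_windows == 48

    def test_rms_of_constant_window(self, tiny_schedule):
        rec = _task_recording(np.full(40 * FS, 3.0))
        ws = make_windows(rec, tiny_schedule)
        assert all(w.rms_uv == pytest.approx(3.0) for w in ws.windows)

    def test_rms_of_integer_cycle_sine_is_closed_form(self, tiny_schedule):
        t = np.arange(40 * FS) / FS
        a = 8.0
        rec = _task_recording(a * np.sin(2 * np.pi * 10 * t))
        ws = make_windows(rec, tiny_schedule)
        for w in ws.windows:
            assert w.rms_uv == pytest.approx(a / np.sqrt(2), abs=1e-6)

    def test_window_labels_follow_alternating_blocks(self, tiny_schedule):
        rec = _task_recording(np.zeros(40 * FS))
        labels = [w.label for w in make_windows(rec, tiny_schedule).windows]
        assert labels == ["stimulus_sentence"] * 2 + ["control_sentence"] * 2 + \
            ["stimulus_sentence"] * 2 + ["control_sentence"] * 2

    def test_window_partition_reconstructs_signal(self, tiny_schedule):
        rng = np.random.default_rng(5)
        data = rng.standard_normal(40 * FS)
        ws = make_windows(_task_recording(data), tiny_schedule)
        rebuilt = np.concatenate([ws.window_samples(w) for w in ws.windows])
        np.testing.assert_array_equal(rebuilt, data)

    def test_trailing_partial_window_dropped(self, tiny_schedule):
        ws = make_windows(_task_recording(np.zeros(12 * FS)), tiny_schedule)
        assert ws.n_windows == 2

    def test_recording_shorter_than_one_window_rejected(self, tiny_schedule):
        with pytest.raises(ValueError, match="shorter"):
            make_windows(_task_recording(np.zeros(FS)), tiny_schedule)


class TestFlagArtifacts:
    def _ws(self, data, schedule):
        return make_windows(_task_recording(data), schedule)

    def test_identical_windows_none_flagged(self, tiny_schedule):
        t = np.arange(40 * FS) / FS
        ws = self._ws(10 * np.sin(2 * np.pi * 10 * t), tiny_schedule)
        out = flag_artifacts(ws)
        assert not any(w.artifact for w in out.windows)

    def test_injected_burst_flags_exactly_that_window(self, tiny_schedule):
        rng = np.random.default_rng(2)
        data = 10.0 * rng.standard_normal(40 * FS)
        target = 5
        data[target * 5 * FS + 100] += 500.0
        out = flag_artifacts(self._ws(data, tiny_schedule))
        flagged = [w.index for w in out.windows if w.artifact]
        assert flagged == [target]

    def test_vacuous_thresholds_flag_nothing(self, tiny_schedule):
        rng = np.random.default_rng(3)
        data = 10.0 * rng.standard_normal(40 * FS)
        data[100] += 500.0
        out = flag_artifacts(self._ws(data, tiny_schedule),
                             k_mad=np.inf, amp_abs_uv=np.inf)
        assert not any(w.artifact for w in out.windows)

    def test_rule_is_idempotent(self, tiny_schedule):
        rng = np.random.default_rng(4)
        data = 10.0 * rng.standard_normal(40 * FS)
        data[2000] += 400.0
        once = flag_artifacts(self._ws(data, tiny_schedule))
        twice = flag_artifacts(once)
        assert [w.artifact for w in once.windows] == \
            [w.artifact for w in twice.windows]

    def test_flags_monotone_in_thresholds(self, tiny_schedule):
        rng = np.random.default_rng(6)
        data = 20.0 * rng.standard_normal(40 * FS)
        ws = self._ws(data, tiny_schedule)
        loose = {w.index for w in flag_artifacts(ws, 5, 150).windows
                 if w.artifact}
        tight = {w.index for w in flag_artifacts(ws, 2, 40).windows
                 if w.artifact}
        assert loose <= tight

    def test_degenerate_mad_falls_back_to_amplitude_rule(self, tiny_schedule):
        data = np.full(40 * FS, 0.0)
        data[100] = 500.0  # single spike: every window RMS differs, but
        # constant-windows channel has MAD 0 after the spike dominates one
        ws = self._ws(data, tiny_schedule)
        out = flag_artifacts(ws)
        assert [w.index for w in out.windows if w.artifact] == [0]

    def test_too_few_windows_rejected(self):
        from aphasia_eeg import build_schedule
        sched = build_schedule(5, 1, 10, [])
        ws = make_windows(_task_recording(np.zeros(10 * FS)), sched)
        with pytest.raises(ValueError, match="at least 4"):
            flag_artifacts(ws)
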