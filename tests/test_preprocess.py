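"""Filtering, epoching, rejection, inclusion and rest-event padding."""

import numpy as np
import pytest

from nrfage.preprocess import (HIGHPASS_01, LOWPASS_12, LOWPASS_30, FilterSpec,
                               PreprocessConfig, apply_fir, design_fir,
                               enforce_inclusion, epoch_and_baseline,
                               pad_resting_events, reject_artifacts)
from nrfage.pipeline import preprocess_recording

from conftest import make_recording

FS = 2000.0
CFG = PreprocessConfig()


class TestFIR:
    def test_dc_gain_unity_for_lowpass(self):
        x = np.full(8000, 3.7)
        y = apply_fir(x, LOWPASS_30, FS)
        mid = y[2000:-2000]
        np.testing.assert_allclose(mid, 3.7, rtol=1e-6)

    def test_stopband_attenuation_at_50hz(self):
        taps = design_fir(LOWPASS_30, FS)
        freqs = np.fft.rfftfreq(1 << 16, 1 / FS)
        h = np.abs(np.fft.rfft(taps, 1 << 16))
        gain_50 = h[np.argmin(np.abs(freqs - 50.0))]
        assert 20 * np.log10(gain_50) < -20

    @pytest.mark.parametrize("spec,f_cut", [(LOWPASS_30, 33.75), (LOWPASS_12, 13.5)])
    def test_half_gain_at_cutoff(self, spec, f_cut):
        """Windowed-sinc convention: magnitude response ~0.5 at the cutoff."""
        taps = design_fir(spec, FS)
        freqs = np.fft.rfftfreq(1 << 16, 1 / FS)
        h = np.abs(np.fft.rfft(taps, 1 << 16))
        assert h[np.argmin(np.abs(freqs - f_cut))] == pytest.approx(0.5, abs=0.05)

    def test_passband_idempotence(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        once = apply_fir(x, LOWPASS_30, FS)
        twice = apply_fir(once, LOWPASS_30, FS)
        mid = slice(2000, -2000)
        amp1 = np.abs(once[mid]).max()
        amp2 = np.abs(twice[mid]).max()
        assert amp2 == pytest.approx(amp1, rel=0.02)

    def test_zero_phase_no_latency_shift(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.exp(-((t - 2.0) ** 2) / (2 * 0.05**2))  # smooth pulse at t=2
        y = apply_fir(x, LOWPASS_30, FS)
        assert abs(np.argmax(y) - np.argmax(x)) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            apply_fir(np.zeros(100), LOWPASS_30, 60.0)


class TestEpoching:
    def test_constant_signal_baselines_to_zero(self):
        rec = make_recording({"Cz": np.full(int(10 * FS), 42.0)}, FS, [("visual", 5.0)])
        es = epoch_and_baseline(rec, "visual", "Cz", CFG)
        assert es.data.shape == (1, int(2 * FS))
        np.testing.assert_array_equal(es.data, 0.0)

    def test_epoch_sample_arithmetic(self):
        """Half-open [t-1, t+1) at 1 kHz covers samples 4000..5999."""
        fs = 1000.0
        x = np.arange(int(10 * fs), dtype=float)
        rec = make_recording({"Cz": x}, fs, [("visual", 5.0)])
        es = epoch_and_baseline(rec, "visual", "Cz", CFG)
        assert es.data.shape == (1, 2000)
        # baseline window [-0.5, 0) has mean sample index 4749.5
        np.testing.assert_allclose(es.data[0], np.arange(4000, 6000) - 4749.5)

    def test_event_too_close_to_edge_flagged(self):
        rec = make_recording({"Cz": np.zeros(int(10 * FS))}, FS,
                             [("visual", 0.5), ("visual", 5.0)])
        es = epoch_and_baseline(rec, "visual", "Cz", CFG)
        assert es.n_trials == 2
        assert not es.kept[0] and es.reject_reason[0] == "unepochable"
        assert es.kept[1]

    def test_no_events_warns_and_returns_empty(self):
        rec = make_recording({"Cz": np.zeros(int(10 * FS))}, FS, [("rest", 5.0)])
        with pytest.warns(UserWarning):
            es = epoch_and_baseline(rec, "visual", "Cz", CFG)
        assert es.n_trials == 0


class TestRejection:
    def _epochs(self, baseline_peaks):
        n = int(2 * FS)
        rec_sig = np.zeros(int((len(baseline_peaks) * 12 + 10) * FS))
        events = []
        fs = int(FS)
        for i, peak in enumerate(baseline_peaks):
            onset = 5.0 + 12.0 * i
            events.append(("visual", onset))
            rec_sig[int(onset * FS) - fs // 2] = peak  # spike in pre-stimulus window
        rec = make_recording({"Cz": rec_sig}, FS, events)
        return epoch_and_baseline(rec, "visual", "Cz", CFG)

    def test_threshold_is_strict(self):
        es = reject_artifacts(self._epochs([200.0, 150.0, 0.0]), CFG)
        assert list(es.kept) == [False, True, True]
        assert es.reject_reason[0] == "amplitude"

    def test_exact_threshold_boundary_kept(self):
        from nrfage.preprocess import EpochSet
        n = int(2 * FS)
        data = np.zeros((3, n))
        data[0, 100] = 150.0  # exactly at threshold -> kept
        data[1, 100] = 150.001  # strictly exceeds -> rejected
        times = -1.0 + np.arange(n) / FS
        es = EpochSet("r", "s", 240, "visual", "Cz", FS, data, times,
                      np.ones(3, bool), [""] * 3)
        out = reject_artifacts(es, CFG)
        assert list(out.kept) == [True, False, True]

    def test_rejection_preserves_samples_and_counts(self):
        before = self._epochs([200.0, 10.0])
        after = reject_artifacts(before, CFG)
        np.testing.assert_array_equal(before.data, after.data)
        assert after.n_kept + (~after.kept).sum() == after.n_trials


class TestInclusion:
    def _epochset(self, rec_id, modality, n_clean, n_total=12):
        kept = np.zeros(n_total, bool)
        kept[:n_clean] = True
        from nrfage.preprocess import EpochSet
        return EpochSet(rec_id, "sub", 240, modality, "Cz", FS,
                        np.zeros((n_total, 10)), np.zeros(10), kept, [""] * n_total)

    def test_fewer_than_five_clean_excludes_modality(self):
        rep = enforce_inclusion([self._epochset("r1", "visual", 4),
                                 self._epochset("r1", "tactile", 10)], CFG)
        vis = rep[(rep.recording == "r1") & (rep.modality == "visual")].iloc[0]
        tac = rep[(rep.recording == "r1") & (rep.modality == "tactile")].iloc[0]
        assert not vis.included and tac.included
        assert vis.recording_included  # retained for tactile only

    def test_five_clean_is_retained(self):
        rep = enforce_inclusion([self._epochset("r1", "visual", 5)], CFG)
        assert rep.iloc[0].included

    def test_recording_dropped_when_all_modalities_fail(self):
        rep = enforce_inclusion([self._epochset("r1", "visual", 2),
                                 self._epochset("r1", "tactile", 3)], CFG)
        assert not rep.recording_included.any()


class TestRestPadding:
    def _rec(self, rest_onsets, duration=400.0):
        events = [("rest", t) for t in rest_onsets] + [("visual", duration - 50)]
        return make_recording({"Cz": np.zeros(int(duration * 500))}, 500.0, events)

    def test_sparse_rest_events_padded(self):
        rec = pad_resting_events(self._rec([200.0, 250.0, 300.0]), CFG)
        onsets = sorted(e.onset_s for e in rec.events_of("rest"))
        assert len(onsets) == 13
        assert onsets[:10] == [100.0 + 10 * k for k in range(10)]

    def test_six_rest_events_unchanged(self):
        rec = self._rec([200 + 10 * k for k in range(6)])
        assert pad_resting_events(rec, CFG) is rec

    def test_padding_clips_to_epochable_range(self):
        with pytest.warns(UserWarning, match="padded rest"):
            rec = pad_resting_events(self._rec([15.0]), CFG)
        onsets = sorted(e.onset_s for e in rec.events_of("rest"))
        assert onsets == [5.0, 15.0]  # only one padded event fits


def test_filter_branches_differ_above_12hz():
    """The NRF branch carries the extra 12 Hz low-pass; the broadband
    (magnitude) branch keeps 20 Hz content."""
    fs = 500.0
    t = np.arange(int(120 * fs)) / fs
    sig = 50.0 * np.sin(2 * np.pi * 20.0 * t)
    events = [("visual", 30.0), ("tactile", 40.0), ("rest", 50.0),
              ("rest", 60.0), ("rest", 70.0), ("rest", 80.0),
              ("rest", 90.0), ("rest", 100.0)]
    rec = make_recording({"Cz": sig, "Oz": sig}, fs, events)
    branches = preprocess_recording(rec, CFG)["visual"]
    bb_amp = np.abs(branches.stim_bb.data).max()
    nrf_amp = np.abs(branches.stim_nrf.data).max()
    assert bb_amp > 25.0  # 20 Hz inside 0.1-30 Hz band
    assert nrf_amp < 0.1 * bb_amp  # strongly attenuated by the 12 Hz low-pass
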