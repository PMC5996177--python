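import numpy as np
import pytest
from scipy import signal as sps

from noisyecg import EcgSignal
from noisyecg.detect import (modified_pt_detect, original_pt_detect,
                             preprocess_qrs, refine_rpeaks)
from noisyecg.quality import QualityMask
from noisyecg.synthesize import NoiseSpec, SynthParams, corrupt, synth_ecg

from conftest import match_stats


class TestPreprocess:
    def test_constant_input_yields_zero_traces(self):
        # past the causal filters' step transient every trace is zero
        tr = preprocess_qrs(EcgSignal(np.full(5000, 3.0), fs=500.0))
        assert np.allclose(tr.derivative[2500:], 0, atol=1e-8)
        assert np.allclose(tr.detection[2500:], 0, atol=1e-8)
        assert np.allclose(tr.upper_thr[-100:], 0, atol=1e-6)

    def test_bandpass_gains_in_and_out_of_band(self):
        # evaluate the designed filter's magnitude response numerically
        sos = sps.butter(1, (5.0, 15.0), btype="bandpass", fs=1000.0,
                         output="sos")
        w, h = sps.sosfreqz(sos, worN=[10.0, 60.0], fs=1000.0)
        assert abs(h[0]) > 0.7     # 10 Hz inside the passband
        assert abs(h[1]) < 0.2     # 60 Hz attenuated (first-order skirt)
        assert abs(h[1]) < 0.3 * abs(h[0])

    def test_threshold_ratio_constant(self, clean_ecg_500hz):
        sig, _ = clean_ecg_500hz
        tr = preprocess_qrs(sig)
        nz = tr.lower_thr > 0
        np.testing.assert_allclose(tr.upper_thr[nz] / tr.lower_thr[nz],
                                   1.25 / 0.3, rtol=1e-9)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            preprocess_qrs(EcgSignal(np.ones(500), fs=50.0))


class TestModifiedPt:
    def test_metronomic_rr_beat_count_and_accuracy(self):
        params = SynthParams(fs=500.0, duration_s=150.0, hr_bpm=60.0,
                             sdnn_ms=0.0, seed=11)
        sig, truth = synth_ecg(params)
        tr = preprocess_qrs(sig)
        beats = refine_rpeaks(modified_pt_detect(sig, trace=tr), tr, sig)
        assert truth.r_times_s.size - 1 <= len(beats) <= truth.r_times_s.size
        errs = np.array([np.min(np.abs(beats.times() - t))
                         for t in truth.r_times_s])
        assert np.all(errs <= 0.010)

    def test_refractory_suppresses_close_smaller_peak(self, clean_ecg_500hz):
        # an extra 150-ms-late bump is suppressed; only the larger survives
        sig, truth = clean_ecg_500hz
        x = sig.samples.copy()
        fs = 500.0
        t_extra = truth.r_times_s[10] + 0.150
        t = np.arange(x.size) / fs
        x += 0.7 * np.exp(-0.5 * ((t - t_extra) / 0.015) ** 2)
        beats = modified_pt_detect(EcgSignal(x, fs=fs))
        gaps = np.diff(beats.r_indices) / fs
        assert np.all(gaps >= 0.2 - 1e-9)
        # the true (larger) beat is the one kept
        near = np.min(np.abs(beats.times() - truth.r_times_s[10]))
        assert near < 0.08

    def test_lower_threshold_recovery_of_attenuated_beat(self, clean_ecg_500hz):
        sig, truth = clean_ecg_500hz
        fs = 500.0
        t = truth.r_times_s[20]
        x = sig.samples.copy()
        x[int((t - 0.45) * fs):int((t + 0.5) * fs)] *= 0.15
        beats = modified_pt_detect(EcgSignal(x, fs=fs))
        det_t = beats.times()
        k = np.argmin(np.abs(det_t - t))
        assert abs(det_t[k] - t) < 0.15
        assert beats.source[k] == "lower_recovered"
        assert len(beats) == truth.r_times_s.size

    def test_rejected_mask_regions_drop_beats(self, clean_ecg_500hz):
        sig, truth = clean_ecg_500hz
        accept = np.ones(sig.n, dtype=bool)
        accept[: sig.n // 2] = False
        mask = QualityMask(accept, sig.fs)
        beats = modified_pt_detect(sig, mask=mask)
        assert np.all(beats.r_indices >= sig.n // 2)

    def test_empty_mask_returns_flagged_empty_set(self, clean_ecg_500hz):
        sig, _ = clean_ecg_500hz
        mask = QualityMask(np.zeros(sig.n, dtype=bool), sig.fs)
        beats = modified_pt_detect(sig, mask=mask)
        assert len(beats) == 0
        assert beats.note == "no analyzable signal"

    def test_amplitude_invariance(self, clean_ecg_500hz):
        sig, _ = clean_ecg_500hz
        a = modified_pt_detect(sig)
        b = modified_pt_detect(EcgSignal(sig.samples * 37.0, fs=sig.fs))
        np.testing.assert_array_equal(a.r_indices, b.r_indices)

    def test_sample_rate_invariance(self):
        times = {}
        for fs in (250.0, 360.0, 1000.0):
            params = SynthParams(fs=fs, duration_s=60.0, hr_bpm=75.0,
                                 sdnn_ms=20.0, seed=12)
            sig, _ = synth_ecg(params)
            tr = preprocess_qrs(sig)
            beats = refine_rpeaks(modified_pt_detect(sig, trace=tr), tr, sig)
            times[fs] = beats.times()
        fss = list(times)
        for i, fa in enumerate(fss):
            for fb in fss[i + 1:]:
                assert times[fa].size == times[fb].size
                tol = 1.0 / min(fa, fb)
                assert np.all(np.abs(times[fa] - times[fb]) <= tol + 1e-9)

    def test_noise_robustness_across_heart_rates(self):
        for hr in (40.0, 90.0, 180.0):
            params = SynthParams(fs=360.0, duration_s=60.0, hr_bpm=hr,
                                 sdnn_ms=30.0, seed=13)
            sig, truth = synth_ecg(params)
            noisy, _ = corrupt(sig, [NoiseSpec("white", snr_db=10.0)], seed=14)
            tr = preprocess_qrs(noisy)
            beats = refine_rpeaks(modified_pt_detect(noisy, trace=tr), tr, noisy)
            se, ppv = match_stats(truth.r_times_s, beats.times())
            assert se >= 0.99 and ppv >= 0.99

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            modified_pt_detect(EcgSignal(np.ones(500), fs=500.0))


class TestRefine:
    def test_displaced_delineation_lands_on_apex(self, clean_ecg_1khz):
        sig, truth = clean_ecg_1khz
        fs = sig.fs
        tr = preprocess_qrs(sig)
        from noisyecg.detect import BeatSet
        true_idx = np.round(truth.r_times_s * fs).astype(np.int64)
        displaced = BeatSet(true_idx + 40, ["upper"] * true_idx.size, fs=fs)
        refined = refine_rpeaks(displaced, tr, sig)
        errs = (refined.r_indices - true_idx) / fs * 1000.0
        assert np.all(np.abs(errs) <= 2.0)

    def test_idempotent_on_already_refined_beats(self, clean_ecg_1khz):
        sig, _ = clean_ecg_1khz
        tr = preprocess_qrs(sig)
        once = refine_rpeaks(modified_pt_detect(sig, trace=tr), tr, sig)
        twice = refine_rpeaks(once, tr, sig)
        assert np.max(np.abs(once.r_indices - twice.r_indices)) <= 1

    def test_inverted_r_wave_refined_to_filtered_extremum(self):
        params = SynthParams(fs=1000.0, duration_s=30.0, hr_bpm=70.0,
                             sdnn_ms=0.0, seed=15)
        params.amplitudes["R"] = -1.0
        params.amplitudes["S"] = 0.25
        params.amplitudes["Q"] = 0.10
        sig, truth = synth_ecg(params)
        tr = preprocess_qrs(sig)
        beats = refine_rpeaks(modified_pt_detect(sig, trace=tr), tr, sig)
        delay = int(round(2 + tr.bandpass_delay))
        for r in beats.r_indices[1:-1]:
            # brute-force extremum of the filtered trace near the beat
            w = slice(int(r) + delay - 40, int(r) + delay + 41)
            ext = np.argmax(np.abs(tr.filtered[w]))
            assert abs(ext - 40) <= 4   # refined point sits at the extremum


class TestOriginalPt:
    def test_clean_sixty_bpm_matches_modified_count(self):
        params = SynthParams(fs=360.0, duration_s=60.0, hr_bpm=60.0,
                             sdnn_ms=10.0, seed=16)
        sig, _ = synth_ecg(params)
        assert len(original_pt_detect(sig)) == len(modified_pt_detect(sig))

    def test_flat_line_yields_no_beats(self):
        beats = original_pt_detect(EcgSignal(np.zeros(72000) + 0.5, fs=360.0))
        assert len(beats) == 0

    def test_refractory_enforced(self):
        params = SynthParams(fs=360.0, duration_s=60.0, hr_bpm=180.0,
                             sdnn_ms=20.0, seed=17)
        sig, _ = synth_ecg(params)
        beats = original_pt_detect(sig)
        assert np.all(np.diff(beats.r_indices) >= 0.2 * 360.0 - 0.5)
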