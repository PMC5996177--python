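import numpy as np
import pytest

from noisyecg.evaluate import _max_matching_count
from noisyecg.synthesize import SynthParams, synth_ecg


@pytest.fixture(scope="session")
def clean_ecg_1khz():
    """150-s clean sinus recording at 75 bpm, fs 1000 Hz, with truth."""
    params = SynthParams(fs=1000.0, duration_s=150.0, hr_bpm=75.0,
                         sdnn_ms=20.0, seed=42)
    return synth_ecg(params)


@pytest.fixture(scope="session")
def clean_ecg_500hz():
    """60-s clean sinus recording at 60 bpm with zero HRV (metronomic RR)."""
    params = SynthParams(fs=500.0, duration_s=60.0, hr_bpm=60.0,
                         sdnn_ms=0.0, seed=3)
    return synth_ecg(params)


def match_stats(ref_times, det_times, window_s=0.1):
    """(Se, PPV) of detected beat times against reference times."""
    ref = np.asarray(ref_times, dtype=float)
    det = np.asarray(det_times, dtype=float)
    tp, _ = _max_matching_count(ref, det, window_s)
    se = tp / ref.size if ref.size else float("nan")
    ppv = tp / det.size if det.size else float("nan")
    return se, ppv
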