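"""Synthetic sinus-rhythm ECG with analytic ground truth.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) whose centres
and widths realise a requested QRS duration and QT interval, so every
fiducial (R apex, Q onset, S end, T end) is known exactly.  The RR
process is i.i.d. normal (truncated at three standard deviations), which
is sufficient for SDNN — the only HRV statistic in scope.

Four corruption families emulate the failure modes of dry-electrode
recordings: in-band EMG-like bursts, impulsive motion spikes, baseline
wander, and powerline interference; plus stationary white noise at a
requested SNR.  Every altered span is recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import EcgSignal

__all__ = ["SynthParams", "GroundTruth", "NoiseSpec", "synth_ecg", "corrupt"]


@dataclass
class SynthParams:
    """Generator settings for one synthetic recording.

    Defaults emulate the study's 150-s resting recordings of a healthy
    adult: 75 bpm sinus rhythm with moderate HRV, 90-ms QRS, 400-ms QT.
    """

    fs: float = 1000.0
    duration_s: float = 150.0
    hr_bpm: float = 75.0
    sdnn_ms: float = 20.0
    qrs_ms: float = 90.0
    qt_ms: float = 400.0
    #: per-wave peak amplitudes in mV
    amplitudes: dict = field(default_factory=lambda: {
        "P": 0.12, "Q": -0.10, "R": 1.00, "S": -0.25, "T": 0.30})
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30 <= self.hr_bpm <= 220:
            raise ValueError(f"hr_bpm must lie in [30, 220], got {self.hr_bpm}")
        if not self.qrs_ms < self.qt_ms:
            raise ValueError("qrs_ms must be shorter than qt_ms")
        if self.fs < 100:
            raise ValueError("fs must be at least 100 Hz")
        if self.sdnn_ms < 0 or self.duration_s <= 0:
            raise ValueError("sdnn_ms must be >= 0 and duration_s > 0")


@dataclass
class GroundTruth:
    """True beat times and injected-corruption bookkeeping."""

    r_times_s: np.ndarray
    rr_s: np.ndarray
    #: (start_s, end_s, kind) spans altered by :func:`corrupt`
    noise_spans: list[tuple[float, float, str]] = field(default_factory=list)
    #: fiducials relative to each R apex, ms
    q_onset_ms: float = 0.0
    s_end_ms: float = 0.0
    t_end_ms: float = 0.0

    def __post_init__(self) -> None:
        self.r_times_s = np.asarray(self.r_times_s, dtype=float)
        self.rr_s = np.asarray(self.rr_s, dtype=float)
        if self.r_times_s.size and np.any(np.diff(self.r_times_s) <= 0):
            raise ValueError("r_times_s must be strictly increasing")


def _wave_layout(qrs_ms: float, qt_ms: float):
    """Per-wave (centre_ms, sigma_ms) relative to the R apex.

    Chosen so that Q onset = -qrs/2, S end = +qrs/2 and T end =
    qt - qrs/2 when onsets/ends are read two sigma out from the
    flanking wave centres.
    """
    qrs, qt = float(qrs_ms), float(qt_ms)
    sig_q = sig_s = qrs / 8.0
    layout = {
        "Q": (-qrs / 2.0 + 2.0 * sig_q, sig_q),
        "R": (0.0, qrs / 6.0),
        "S": (qrs / 2.0 - 2.0 * sig_s, sig_s),
        "T": (qt - qrs / 2.0 - 2.0 * 30.0, 30.0),
        "P": (-160.0, 22.0),
    }
    fiducials = {"q_onset_ms": -qrs / 2.0, "s_end_ms": qrs / 2.0,
                 "t_end_ms": qt - qrs / 2.0}
    return layout, fiducials


def synth_ecg(params: SynthParams) -> tuple[EcgSignal, GroundTruth]:
    """Render a synthetic sinus-rhythm recording with known R apices."""
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    mean_rr = 60.0 / params.hr_bpm
    sd_rr = params.sdnn_ms / 1000.0

    # draw RR intervals until the record is covered
    n_guess = int(np.ceil(params.duration_s / mean_rr)) + 8
    rr = rng.normal(mean_rr, sd_rr, size=n_guess)
    if sd_rr > 0:
        rr = np.clip(rr, mean_rr - 3 * sd_rr, mean_rr + 3 * sd_rr)
    first = 0.4 * mean_rr  # leave room for the P wave of the first beat
    r_times = first + np.concatenate([[0.0], np.cumsum(rr)])
    margin = params.qt_ms / 1000.0  # keep the last T wave inside the record
    r_times = r_times[r_times < params.duration_s - margin]
    rr_kept = np.diff(r_times)

    layout, fid = _wave_layout(params.qrs_ms, params.qt_ms)
    n = int(round(params.duration_s * fs))
    x = np.zeros(n)
    t = np.arange(n) / fs
    for wave, (centre_ms, sigma_ms) in layout.items():
        amp = params.amplitudes.get(wave, 0.0)
        if amp == 0.0:
            continue
        sigma = sigma_ms / 1000.0
        half = int(np.ceil(4 * sigma * fs))
        for rt in r_times:
            c = rt + centre_ms / 1000.0
            i0 = max(0, int(np.floor((c * fs))) - half)
            i1 = min(n, int(np.ceil((c * fs))) + half + 1)
            if i0 >= i1:
                continue
            x[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - c) / sigma) ** 2)

    sig = EcgSignal(x, fs=fs, lead="synthetic")
    truth = GroundTruth(r_times, rr_kept, **fid)
    return sig, truth


@dataclass
class NoiseSpec:
    """One corruption to inject.

    kind: ``white`` (snr_db over whole record), ``emg`` (band-limited
    burst over [start_s, end_s] at snr_db relative to signal power),
    ``spikes`` (count impulses of ``amplitude`` mV at random times),
    ``baseline`` (sinusoidal wander, ``freq_hz`` <= 0.5), or
    ``powerline`` (mains sinusoid, default 60 Hz).
    """

    kind: str
    start_s: float | None = None
    end_s: float | None = None
    snr_db: float | None = None
    amplitude: float | None = None
    count: int | None = None
    freq_hz: float | None = None


def _band(spec: NoiseSpec, duration: float) -> tuple[float, float]:
    a = 0.0 if spec.start_s is None else spec.start_s
    b = duration if spec.end_s is None else spec.end_s
    if not 0 <= a < b <= duration + 1e-9:
        raise ValueError(f"noise span [{a}, {b}] outside the record")
    return a, b


def corrupt(signal: EcgSignal, kinds: list[NoiseSpec],
            seed: int = 0) -> tuple[EcgSignal, GroundTruth]:
    """Add the requested corruptions; return the noisy signal plus spans.

    The returned GroundTruth carries only the noise bookkeeping (beat
    truth is unchanged by corruption and remains with the generator).
    """
    rng = np.random.default_rng(seed)
    fs, n = signal.fs, signal.n
    duration = signal.duration_s
    x = signal.samples.copy()
    sig_power = float(np.mean(signal.samples ** 2))
    spans: list[tuple[float, float, str]] = []

    for spec in kinds:
        if spec.kind == "white":
            if spec.snr_db is None:
                raise ValueError("white noise needs snr_db")
            noise_power = sig_power / (10.0 ** (spec.snr_db / 10.0))
            x += rng.normal(0.0, np.sqrt(noise_power), size=n)
            spans.append((0.0, duration, "white"))
        elif spec.kind == "emg":
            a, b = _band(spec, duration)
            snr = 0.0 if spec.snr_db is None else spec.snr_db
            noise_power = sig_power / (10.0 ** (snr / 10.0))
            i0, i1 = int(a * fs), int(b * fs)
            burst = rng.normal(0.0, 1.0, size=i1 - i0)
            sos = sps.butter(4, [5.0, 40.0], btype="bandpass", fs=fs, output="sos")
            burst = sps.sosfiltfilt(sos, burst)
            burst *= np.sqrt(noise_power / np.mean(burst ** 2))
            x[i0:i1] += burst
            spans.append((a, b, "emg"))
        elif spec.kind == "spikes":
            count = spec.count or 1
            amp = spec.amplitude if spec.amplitude is not None else \
                10.0 * float(np.std(signal.samples))
            a, b = _band(spec, duration)
            lo, hi = int(a * fs), int(b * fs)
            pos = rng.choice(np.arange(lo, hi), size=count, replace=False)
            width = max(1, int(round(0.01 * fs)))  # 10-ms impulses
            for p in np.sort(pos):
                j1 = min(n, p + width)
                x[p:j1] += amp * np.sign(rng.standard_normal())
                spans.append((p / fs, j1 / fs, "spike"))
        elif spec.kind == "baseline":
            freq = spec.freq_hz if spec.freq_hz is not None else 0.3
            if freq > 0.5:
                raise ValueError("baseline wander must stay at or below 0.5 Hz")
            amp = spec.amplitude if spec.amplitude is not None else 0.5
            t = signal.times()
            phase = rng.uniform(0, 2 * np.pi)
            x += amp * np.sin(2 * np.pi * freq * t + phase)
            spans.append((0.0, duration, "baseline"))
        elif spec.kind == "powerline":
            freq = spec.freq_hz if spec.freq_hz is not None else 60.0
            amp = spec.amplitude if spec.amplitude is not None else 0.05
            t = signal.times()
            phase = rng.uniform(0, 2 * np.pi)
            x += amp * np.sin(2 * np.pi * freq * t + phase)
            spans.append((0.0, duration, "powerline"))
        else:
            raise ValueError(f"unknown noise kind {spec.kind!r}")

    noisy = replace(signal, samples=x)
    return noisy, GroundTruth(np.asarray([]), np.asarray([]), noise_spans=spans)
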