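"""Signal-quality classification: accept or reject ("shutdown") every sample.

Two signal-quality indices, both computed on the 5-15 Hz bandpassed ECG
used by the QRS detector:

* moving kurtosis over a 2-s window — Pearson convention, i.e. the
  fourth central moment over the squared variance, so a normal
  distribution scores 3.  A clean sinus ECG is dominated by its sharp
  QRS complexes and scores well above 5; in-band noise pulls the value
  toward 3, and windows below an empirical threshold of 3.6 are
  rejected.
* moving standard deviation over the same window — large-amplitude
  motion spikes inflate the local SD; windows whose SD exceeds 1.5x the
  whole-record SD are rejected.

Rejected runs shorter than a bridge gap are forgiven, accepted runs
shorter than a minimum length are dropped, and the survivors form the
accepted segments of the QualityMask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EcgSignal

__all__ = ["SqiSeries", "QualityMask", "moving_kurtosis", "spike_sqi",
           "quality_mask", "mask_to_frame"]


@dataclass
class SqiSeries:
    """Per-sample signal-quality index values."""

    values: np.ndarray
    kind: str                 # "kurtosis" | "moving_sd"
    window_s: float
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class QualityMask:
    """Per-sample accept/reject classification plus accepted segments."""

    accept: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.accept = np.asarray(self.accept, dtype=bool)

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Half-open (start, end) sample runs where accept is True."""
        a = self.accept.astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], a, [0]])))
        return [(int(edges[i]), int(edges[i + 1]))
                for i in range(0, edges.size, 2)]

    @property
    def pass_fraction(self) -> float:
        return float(self.accept.mean()) if self.accept.size else 0.0

    def rejected_spans_s(self) -> list[tuple[float, float]]:
        r = QualityMask(~self.accept, self.fs)
        return [(s / self.fs, e / self.fs) for s, e in r.segments]


def _moving_moments(x: np.ndarray, half: int, powers: tuple[int, ...]):
    """Centred moving means of x**p with windows clipped at the record
    edges (so edge windows shrink, never below half length)."""
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    count = (hi - lo).astype(float)
    out = {}
    for p in powers:
        c = np.concatenate([[0.0], np.cumsum(x ** p)])
        out[p] = (c[hi] - c[lo]) / count
    return out


def _window_half(window_s: float, fs: float) -> int:
    return int(round(window_s * fs / 2.0))


def moving_kurtosis(signal: EcgSignal, window_s: float = 2.0) -> SqiSeries:
    """Per-sample Pearson kurtosis over a centred window.

    The signal is expected to be the QRS-band filtered trace (see
    :func:`noisyecg.detect.qrs_bandpass`); the statistic itself is
    shift-invariant, so the global mean is removed first for numerical
    conditioning.  Windows with zero variance yield NaN.
    """
    fs = signal.fs
    if window_s * fs < 4:
        raise ValueError("kurtosis window must span at least 4 samples")
    if window_s * fs > signal.n:
        raise ValueError("window longer than the signal")
    x = signal.samples - signal.samples.mean()
    half = _window_half(window_s, fs)
    m = _moving_moments(x, half, (1, 2, 3, 4))
    mu = m[1]
    m2 = m[2] - mu ** 2
    m4 = m[4] - 4 * mu * m[3] + 6 * mu ** 2 * m[2] - 3 * mu ** 4
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2, np.nan)
    return SqiSeries(kurt, "kurtosis", window_s, fs)


def spike_sqi(signal: EcgSignal, window_s: float = 2.0) -> SqiSeries:
    """Per-sample moving standard deviation over a centred window.

    The associated rejection rule (applied by :func:`quality_mask`) is
    value > k x SD(entire signal), so the mask is invariant under
    amplitude scaling.
    """
    fs = signal.fs
    if signal.n == 0:
        raise ValueError("empty signal")
    if window_s * fs < 2:
        raise ValueError("moving-SD window must span at least 2 samples")
    x = signal.samples - signal.samples.mean()
    half = _window_half(window_s, fs)
    m = _moving_moments(x, half, (1, 2))
    var = np.maximum(m[2] - m[1] ** 2, 0.0)
    return SqiSeries(np.sqrt(var), "moving_sd", window_s, fs)


def quality_mask(signal: EcgSignal,
                 kurtosis_threshold: float = 3.6,
                 sd_multiplier: float = 1.5,
                 window_s: float = 2.0,
                 min_segment_s: float = 2.0,
                 bridge_s: float = 0.5,
                 prefiltered: bool = False) -> QualityMask:
    """Classify every sample using both signal-quality indices.

    A sample is accepted iff its moving kurtosis exceeds
    ``kurtosis_threshold`` and its moving SD does not exceed
    ``sd_multiplier`` times the whole-record SD, both computed on the
    QRS-band (5-15 Hz) filtered signal.  Pass ``prefiltered=True`` when
    ``signal`` already is that filtered trace.  Rejected runs shorter
    than ``bridge_s`` are forgiven; accepted runs shorter than
    ``min_segment_s`` are dropped.
    """
    if kurtosis_threshold <= 0 or sd_multiplier <= 0:
        raise ValueError("thresholds must be positive")
    if signal.n <= window_s * signal.fs:
        raise ValueError("signal must be longer than the SQI window")
    if prefiltered:
        filt = signal
    else:
        from .detect import qrs_bandpass
        filt = EcgSignal(qrs_bandpass(signal), fs=signal.fs, lead=signal.lead) \
            if np.ptp(signal.samples) > 0 else None
    if filt is None or np.ptp(filt.samples) == 0:
        # constant signal: kurtosis undefined everywhere -> reject all
        return QualityMask(np.zeros(signal.n, dtype=bool), signal.fs)

    kurt = moving_kurtosis(filt, window_s).values
    msd = spike_sqi(filt, window_s).values
    global_sd = float(filt.samples.std())
    if global_sd == 0:
        return QualityMask(np.zeros(signal.n, dtype=bool), signal.fs)

    accept = np.nan_to_num(kurt, nan=-np.inf) > kurtosis_threshold
    accept &= msd <= sd_multiplier * global_sd

    fs = signal.fs
    accept = _bridge_short_rejections(accept, int(round(bridge_s * fs)))
    accept = _drop_short_acceptances(accept, int(round(min_segment_s * fs)))
    return QualityMask(accept, fs)


def _runs(mask: np.ndarray, value: bool) -> list[tuple[int, int]]:
    a = (mask == value).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], a, [0]])))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def _bridge_short_rejections(accept: np.ndarray, max_len: int) -> np.ndarray:
    out = accept.copy()
    for s, e in _runs(accept, False):
        # only interior rejections are bridged; edge runs stay rejected
        if e - s < max_len and s > 0 and e < accept.size:
            out[s:e] = True
    return out


def _drop_short_acceptances(accept: np.ndarray, min_len: int) -> np.ndarray:
    out = accept.copy()
    for s, e in _runs(accept, True):
        if e - s < min_len:
            out[s:e] = False
    return out


def mask_to_frame(mask: QualityMask):
    """Mask as a 3-column table (start_s, end_s, accepted) tiling the record."""
    import pandas as pd

    rows = []
    changes = np.flatnonzero(np.diff(mask.accept.astype(np.int8)))
    boundaries = [0, *(changes + 1).tolist(), mask.accept.size]
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        rows.append({"start_s": s / mask.fs, "end_s": e / mask.fs,
                     "accepted": bool(mask.accept[s])})
    return pd.DataFrame(rows, columns=["start_s", "end_s", "accepted"])
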