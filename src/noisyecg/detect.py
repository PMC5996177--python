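"""QRS detection: modified Pan-Tompkins pipeline, R-peak refinement, and
the classic Pan-Tompkins detector as a comparison baseline.

The modified pipeline processes the raw ECG causally (streaming
heritage): a first-order 5-15 Hz Butterworth bandpass isolates the QRS
band, a five-point derivative and squaring emphasise slope, and a
third-order 8-Hz low-pass replaces the classic moving-window integration
so each QRS yields a single smooth detection lobe.  Dual thresholds
(1.25x and 0.3x a continuously updated 5-s moving average of the
detection trace) delineate beats; the lower threshold recovers beats
missed inside abnormally long inter-beat gaps.  Because all filtering is
causal, delineations land slightly late; the refinement stage walks back
to the true wave apex and compensates the known pipeline delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal as sps

from .io import EcgSignal

if TYPE_CHECKING:  # avoid a runtime cycle: quality uses the bandpass below
    from .quality import QualityMask

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionTrace", "BeatSet",
    "qrs_bandpass", "preprocess_qrs",
    "modified_pt_detect", "refine_rpeaks", "original_pt_detect",
]


@dataclass
class DetectionTrace:
    """Intermediate series of the modified Pan-Tompkins pipeline."""

    filtered: np.ndarray      # 5-15 Hz bandpassed ECG
    derivative: np.ndarray    # five-point derivative of `filtered`
    squared: np.ndarray       # derivative ** 2
    detection: np.ndarray     # 8-Hz low-passed `squared`
    upper_thr: np.ndarray
    lower_thr: np.ndarray
    fs: float
    #: peak delay (samples) the causal bandpass imposes on a QRS-width pulse
    bandpass_delay: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.filtered)
        for name in ("derivative", "squared", "detection", "upper_thr", "lower_thr"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace series {name} length mismatch")


@dataclass
class BeatSet:
    """Ordered R-peak sample indices with provenance flags."""

    r_indices: np.ndarray
    source: np.ndarray        # per-beat: "upper" | "lower_recovered"
    fs: float
    refined: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=np.int64)
        self.source = np.asarray(self.source, dtype=object)
        if self.source.size != self.r_indices.size:
            raise ValueError("source flags must match r_indices length")
        if self.r_indices.size > 1:
            gaps = np.diff(self.r_indices)
            if np.any(gaps <= 0):
                raise ValueError("r_indices must be strictly increasing")
            min_gap = 0.2 * self.fs
            if np.any(gaps < min_gap - 0.5):
                raise ValueError("beats violate the 200-ms refractory period")

    def __len__(self) -> int:
        return int(self.r_indices.size)

    def times(self) -> np.ndarray:
        return self.r_indices / self.fs

    def rr_s(self) -> np.ndarray:
        return np.diff(self.r_indices) / self.fs


def qrs_bandpass(signal: EcgSignal, band_hz: tuple[float, float] = (5.0, 15.0),
                 order: int = 1) -> np.ndarray:
    """Causal Butterworth bandpass isolating the QRS band (shared with the
    signal-quality stage)."""
    if signal.fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    sos = sps.butter(order, band_hz, btype="bandpass", fs=signal.fs, output="sos")
    return sps.sosfilt(sos, signal.samples)


def _five_point_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    # y[n] = (fs/8) * (2x[n] + x[n-1] - x[n-3] - 2x[n-4]); exact FIR delay 2
    b = (fs / 8.0) * np.array([2.0, 1.0, 0.0, -1.0, -2.0])
    return sps.lfilter(b, [1.0], x)


def _trailing_mean(x: np.ndarray, win: int, min_win: int = 0) -> np.ndarray:
    """Causal moving average; the first `win` samples use an expanding
    window so thresholds exist from the first sample.  Expanding windows
    shorter than `min_win` are unstable (near-zero thresholds admit any
    startup ripple), so those samples inherit the value at `min_win`."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(0, idx - win)
    ma = (c[idx] - c[lo]) / (idx - lo)
    if 0 < min_win < ma.size:
        ma[:min_win] = ma[min_win]
    return ma


def preprocess_qrs(signal: EcgSignal,
                   band_hz: tuple[float, float] = (5.0, 15.0),
                   band_order: int = 1,
                   lowpass_hz: float = 8.0,
                   lowpass_order: int = 3,
                   ma_window_s: float = 5.0,
                   upper_mult: float = 1.25,
                   lower_mult: float = 0.3) -> DetectionTrace:
    """Run the filtering chain and compute the dual detection thresholds."""
    fs = signal.fs
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz for QRS filtering")
    filtered = qrs_bandpass(signal, band_hz, band_order)
    derivative = _five_point_derivative(filtered, fs)
    squared = derivative ** 2
    sos = sps.butter(lowpass_order, lowpass_hz, btype="low", fs=fs, output="sos")
    detection = sps.sosfilt(sos, squared)
    ma = _trailing_mean(detection, max(1, int(round(ma_window_s * fs))),
                        min_win=int(round(fs)))
    delay = _qrs_pulse_delay(band_hz, band_order, fs)
    return DetectionTrace(
        filtered=filtered, derivative=derivative, squared=squared,
        detection=detection, upper_thr=upper_mult * ma, lower_thr=lower_mult * ma,
        fs=fs, bandpass_delay=delay)


def _qrs_pulse_delay(band_hz: tuple[float, float], order: int, fs: float,
                     qrs_ms: float = 90.0) -> float:
    """Residual delay of the causal bandpass, measured as the peak shift
    of its response to a nominal QRS-width Gaussian pulse.  A QRS is
    wideband relative to this filter, so the narrowband group delay is
    not representative; the template measurement is."""
    sigma = qrs_ms / 6.0 / 1000.0
    half = int(round(6 * sigma * fs))
    t = (np.arange(4 * half) - 2 * half) / fs
    pulse = np.exp(-0.5 * (t / sigma) ** 2)
    sos = sps.butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    out = np.abs(sps.sosfilt(sos, pulse))
    p = int(np.argmax(out))
    # parabolic sub-sample peak (the pulse itself is symmetric and exact)
    if 0 < p < out.size - 1:
        denom = out[p - 1] - 2 * out[p] + out[p + 1]
        if denom < 0:
            p = p + 0.5 * (out[p - 1] - out[p + 1]) / denom
    return float(p - np.argmax(pulse))


def _candidate_peaks(detection: np.ndarray, refractory: int) -> np.ndarray:
    """Local maxima taken greedily from largest to smallest amplitude with a
    minimum spacing of one refractory period (scipy's `distance` pruning
    implements exactly this greedy order)."""
    peaks, _ = sps.find_peaks(detection, distance=refractory)
    return peaks


def _local_median_interval(accepted: np.ndarray, centre: float, fs: float,
                           window_s: float = 20.0) -> float | None:
    """Median beat interval over beats within `window_s` of `centre`;
    falls back to the global median when fewer than three beats qualify."""
    if accepted.size < 2:
        return None
    near = accepted[np.abs(accepted - centre) <= window_s * fs]
    if near.size >= 3:
        return float(np.median(np.diff(near)))
    return float(np.median(np.diff(accepted)))


def modified_pt_detect(signal: EcgSignal, mask: "QualityMask | None" = None,
                       trace: DetectionTrace | None = None,
                       refractory_ms: float = 200.0,
                       gap_mult: float = 1.5,
                       median_window_s: float = 20.0,
                       **preprocess_kwargs) -> BeatSet:
    """Delineate R peaks with the dual-threshold modified Pan-Tompkins.

    Candidates above the upper threshold are accepted outright; inside
    any inter-beat gap longer than ``gap_mult`` times the local median
    interval, candidates above the lower threshold are recovered in a
    single pass.  Beats falling in mask-rejected ("shutdown") regions
    are discarded last.
    """
    fs = signal.fs
    if signal.duration_s < 5.0:
        raise ValueError("record must cover at least 5 s (threshold window)")
    if trace is None:
        trace = preprocess_qrs(signal, **preprocess_kwargs)
    refractory = int(round(refractory_ms / 1000.0 * fs))
    det = trace.detection

    candidates = _candidate_peaks(det, refractory)
    above_upper = candidates[det[candidates] > trace.upper_thr[candidates]]
    accepted = np.sort(above_upper)
    source = {int(i): "upper" for i in accepted}

    # single-pass lower-threshold recovery inside long gaps
    if accepted.size >= 2:
        recoverable = candidates[
            (det[candidates] > trace.lower_thr[candidates])
            & (det[candidates] <= trace.upper_thr[candidates])]
        recovered: list[int] = []

        def fill(left: int, right: int, med: float) -> None:
            # recover the largest candidate only while the sub-gap is still
            # implausibly long, then re-examine the two halves; a recovered
            # beat may not leave a sub-interval shorter than half the local
            # median (a real missed beat cannot sit that close to its
            # neighbour, but a T wave can)
            if (right - left) <= gap_mult * med:
                return
            margin = max(refractory, int(0.5 * med))
            inside = recoverable[(recoverable > left + margin)
                                 & (recoverable < right - margin)]
            if inside.size == 0:
                return
            c = int(inside[np.argmax(det[inside])])
            recovered.append(c)
            fill(left, c, med)
            fill(c, right, med)

        for left, right in zip(accepted[:-1], accepted[1:]):
            med = _local_median_interval(accepted, (left + right) / 2.0, fs,
                                         median_window_s)
            if med is not None:
                fill(int(left), int(right), med)
        if recovered:
            for i in recovered:
                source[i] = "lower_recovered"
            accepted = np.sort(np.concatenate([accepted, recovered]).astype(np.int64))

    note = ""
    if mask is not None:
        if not mask.accept.any():
            return BeatSet(np.asarray([], dtype=np.int64),
                           np.asarray([], dtype=object), fs=fs,
                           note="no analyzable signal")
        keep = mask.accept[np.clip(accepted, 0, mask.accept.size - 1)]
        accepted = accepted[keep]
    if accepted.size == 0:
        note = note or "no beats detected"
    return BeatSet(accepted, np.asarray([source[int(i)] for i in accepted],
                                        dtype=object), fs=fs, note=note)


def refine_rpeaks(beats: BeatSet, trace: DetectionTrace,
                  signal: EcgSignal, radius_ms: float = 150.0) -> BeatSet:
    """Refine each delineation to the apex of the bandpassed R wave.

    Within ``radius_ms`` of the original point, the two largest local
    maxima of the squared derivative bound a search window; the refined
    peak is the first zero-crossing of the derivative inside that
    window (the extremum of the filtered ECG).  The known causal delays
    (two samples from the derivative FIR plus the bandpass group delay
    at the QRS band centre) are then subtracted so the index refers to
    the raw-signal apex.
    """
    fs = beats.fs
    radius = int(round(radius_ms / 1000.0 * fs))
    sq, d = trace.squared, trace.derivative
    delay = 2.0 + trace.bandpass_delay
    n = sq.size
    refined: list[int] = []
    for r in beats.r_indices:
        lo, hi = max(1, r - radius), min(n - 1, r + radius + 1)
        seg = sq[lo:hi]
        # strict local maxima of the squared derivative
        peaks, _ = sps.find_peaks(seg)
        if peaks.size < 2:
            logger.warning("refine_rpeaks: fewer than two squared-derivative "
                           "peaks near sample %d; keeping original", r)
            refined.append(int(r))
            continue
        top2 = peaks[np.argsort(seg[peaks])[::-1][:2]] + lo
        w0, w1 = int(top2.min()), int(top2.max())
        zc = None
        for i in range(w0, w1):
            if d[i] == 0.0:
                zc = float(i)
                break
            if d[i] * d[i + 1] < 0:
                # sub-sample crossing by linear interpolation
                zc = i + d[i] / (d[i] - d[i + 1])
                break
        if zc is None:
            refined.append(int(r))
            continue
        refined.append(max(0, int(round(zc - delay))))
    order = np.argsort(refined)
    idx = np.asarray(refined, dtype=np.int64)[order]
    src = beats.source[order]
    # refinement may not break the refractory invariant; dedupe defensively
    keep = np.concatenate([[True], np.diff(idx) >= int(0.2 * fs)])
    return BeatSet(idx[keep], src[keep], fs=fs, refined=True, note=beats.note)


# ---------------------------------------------------------------------------
# Original Pan-Tompkins (1985) baseline
# ---------------------------------------------------------------------------

def _pt_bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    """Cascaded integer low-pass and high-pass of the classic detector,
    with tap spacings scaled from the original 200-Hz design."""
    d1 = max(1, int(round(0.03 * fs)))           # LP: 6 samples at 200 Hz
    b_lp = np.zeros(2 * d1 + 1)
    b_lp[0], b_lp[d1], b_lp[2 * d1] = 1.0, -2.0, 1.0
    lp = sps.lfilter(b_lp, [1.0, -2.0, 1.0], x)
    n_hp = max(2, int(round(0.16 * fs)))         # HP: 32 samples at 200 Hz
    half = n_hp // 2
    run = sps.lfilter(np.ones(n_hp), [1.0], lp) / n_hp
    delayed = np.concatenate([np.zeros(half), lp[:-half]]) if half else lp
    return delayed - run


def original_pt_detect(signal: EcgSignal,
                       refractory_ms: float = 200.0) -> BeatSet:
    """Classic Pan-Tompkins detector: integer-style bandpass, derivative,
    squaring, 150-ms moving-window integration, adaptive signal/noise
    thresholds with search-back.  Comparison baseline only."""
    fs = signal.fs
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    if np.ptp(signal.samples) == 0:
        return BeatSet(np.asarray([], dtype=np.int64),
                       np.asarray([], dtype=object), fs=fs,
                       note="no beats detected")
    x = _pt_bandpass(signal.samples, fs)
    deriv = _five_point_derivative(x, fs)
    sq = deriv ** 2
    w = max(1, int(round(0.15 * fs)))
    mwi = sps.lfilter(np.ones(w) / w, [1.0], sq)

    refractory = int(round(refractory_ms / 1000.0 * fs))
    peaks, _ = sps.find_peaks(mwi, distance=refractory)
    if peaks.size == 0:
        return BeatSet(np.asarray([], dtype=np.int64),
                       np.asarray([], dtype=object), fs=fs,
                       note="no beats detected")

    init = mwi[: int(2 * fs)]
    spki = 0.5 * float(init.max()) if init.size else 0.0
    npki = 0.5 * float(init.mean()) if init.size else 0.0
    rr_hist: list[int] = []
    qrs: list[int] = []
    last_missed_scan = 0
    for p in peaks:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[p] > thr1:
            qrs.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(qrs) > 1:
                rr_hist.append(qrs[-1] - qrs[-2])
                rr_hist = rr_hist[-8:]
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
        # search-back for a missed beat
        if rr_hist and qrs:
            rr_avg = float(np.mean(rr_hist))
            if p - qrs[-1] > 1.66 * rr_avg and qrs[-1] > last_missed_scan:
                seg = peaks[(peaks > qrs[-1] + refractory) & (peaks < p)]
                seg = seg[mwi[seg] > 0.5 * thr1]
                if seg.size:
                    best = int(seg[np.argmax(mwi[seg])])
                    if best != qrs[-1] and p - best >= refractory:
                        qrs.append(best)
                        qrs.sort()
                        spki = 0.25 * mwi[best] + 0.75 * spki
                last_missed_scan = qrs[-1]

    idx = np.unique(np.asarray(qrs, dtype=np.int64))
    # delay compensation: bandpass (~half HP window) + derivative + MWI centre
    delay = int(round(0.16 * fs / 2)) // 2 + 2 + w // 2
    idx = np.clip(idx - delay, 0, signal.n - 1)
    keep = np.concatenate([[True], np.diff(idx) >= refractory]) if idx.size else \
        np.asarray([], dtype=bool)
    idx = idx[keep]
    return BeatSet(idx, np.asarray(["upper"] * idx.size, dtype=object), fs=fs)
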