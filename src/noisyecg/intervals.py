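"""Cardiac interval measures: heart rate, SDNN, QRS duration and QTc.

Heart rate is the reciprocal of the outlier-rejected median RR interval:
RR intervals more than 60% out of tolerance with the initial median are
dropped before the final median.  SDNN is the sample standard deviation
of the (optionally outlier-rejected) RR series.  QRS and QT durations
come from fiducials placed on the ensemble-averaged beat (Q onset, S
end, T end, relative to the R peak); QT is corrected for heart rate
with Bazett's formula, QTc = QT / sqrt(RR) with RR in seconds.

Per-recording validity gates mirror the study protocol: at least 15
beats for heart rate, 60 for SDNN and for the ensemble used in QT/QRS
measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detect import BeatSet

__all__ = ["Fiducials", "IntervalReport", "heart_rate", "sdnn",
           "cardiac_intervals"]


@dataclass
class Fiducials:
    """Manually (or externally) delineated feature times on the ensemble
    beat, in ms relative to the R peak."""

    q_onset_ms: float
    s_end_ms: float
    t_end_ms: float
    source: str = "manual"

    def __post_init__(self) -> None:
        if not self.q_onset_ms < self.s_end_ms < self.t_end_ms:
            raise ValueError(
                "fiducials must satisfy q_onset < s_end < t_end "
                f"(got {self.q_onset_ms}, {self.s_end_ms}, {self.t_end_ms})")

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "external") -> "Fiducials":
        import pandas as pd

        row = pd.read_csv(path).iloc[0]
        return cls(float(row["q_onset_ms"]), float(row["s_end_ms"]),
                   float(row["t_end_ms"]), source=source)


@dataclass
class IntervalReport:
    """Per-recording cardiac measures with validity flags."""

    hr_bpm: float = math.nan
    sdnn_ms: float = math.nan
    qrs_ms: float = math.nan
    qt_ms: float = math.nan
    qtc_ms: float = math.nan
    n_beats_hr: int = 0
    n_beats_hrv: int = 0
    valid_hr: bool = False
    valid_hrv: bool = False
    valid_qt: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(self)])


def _rejected_rr(rr: np.ndarray, tol: float) -> np.ndarray:
    """Drop RR intervals more than ``tol`` out of tolerance with the
    initial median."""
    m = float(np.median(rr))
    return rr[np.abs(rr - m) <= tol * m]


def heart_rate(beats: BeatSet, fs: float | None = None, tol: float = 0.60,
               min_beats: int = 15) -> tuple[float, int, bool]:
    """Median-RR heart rate with +/-60% outlier rejection.

    Returns (hr_bpm, n_beats_used, valid).
    """
    fs = beats.fs if fs is None else fs
    if len(beats) < 2:
        raise ValueError("heart rate needs at least 2 beats")
    rr = np.diff(beats.r_indices) / fs
    kept = _rejected_rr(rr, tol)
    if kept.size == 0:
        raise ValueError("all RR intervals rejected as outliers")
    hr = 60.0 / float(np.median(kept))
    n_used = int(kept.size) + 1
    return hr, n_used, n_used >= min_beats


def sdnn(beats: BeatSet, fs: float | None = None, min_beats: int = 60,
         reject_outliers: bool = True, tol: float = 0.60) -> tuple[float, bool]:
    """SD of the RR series in ms (sample SD, n-1 denominator).

    Sinus-beat restriction is approximated by the same +/-60% RR
    outlier rejection used for heart rate (``reject_outliers``).
    Returns (sdnn_ms, valid).
    """
    fs = beats.fs if fs is None else fs
    if len(beats) < 2:
        raise ValueError("SDNN needs at least 2 beats")
    rr = np.diff(beats.r_indices) / fs
    if reject_outliers:
        rr = _rejected_rr(rr, tol)
    if rr.size < 2:
        return 0.0, False
    value = float(np.std(rr, ddof=1)) * 1000.0
    n_used = int(rr.size) + 1
    return value, n_used >= min_beats


def cardiac_intervals(fid: Fiducials, rr_s: float) -> tuple[float, float, float]:
    """QRS duration, QT and Bazett-corrected QTc, all in ms.

    QRS = S end - Q onset; QT = T end - Q onset; QTc = QT / sqrt(RR)
    with RR in seconds (so QTc = QT at 60 bpm).
    """
    if rr_s <= 0:
        raise ValueError("rr_s must be positive")
    qrs = fid.s_end_ms - fid.q_onset_ms
    qt = fid.t_end_ms - fid.q_onset_ms
    return qrs, qt, qt / math.sqrt(rr_s)
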