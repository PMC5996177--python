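"""End-to-end orchestration of the analysis chain.

``analyze_recording`` runs quality gating, detection, refinement,
interval extraction and (optionally, given fiducials) ensemble-based
QRS/QT measurement on one recording.  ``benchmark_database`` replays
the beat-by-beat validation protocol over a directory of WFDB records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import detect, ensemble, evaluate, intervals, io, quality
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["RecordingAnalysis", "analyze_recording", "benchmark_database"]


@dataclass
class RecordingAnalysis:
    """Everything produced by one run of the chain."""

    report: intervals.IntervalReport
    mask: quality.QualityMask
    beats: detect.BeatSet
    selected: detect.BeatSet | None
    ensemble_beat: ensemble.EnsembleBeat | None
    trace: detect.DetectionTrace


def analyze_recording(signal: io.EcgSignal,
                      config: RunConfig | None = None,
                      fiducials: intervals.Fiducials | None = None
                      ) -> RecordingAnalysis:
    """Run the full chain on one recording.

    Order: quality mask -> modified Pan-Tompkins detection -> R-peak
    refinement -> heart rate / SDNN -> beat selection -> ensemble
    average -> cardiac intervals (when fiducials are supplied).
    """
    cfg = config or RunConfig()
    trace = detect.preprocess_qrs(
        signal, band_hz=cfg.detect_bandpass_hz,
        band_order=cfg.detect_bandpass_order,
        lowpass_hz=cfg.detect_lowpass_hz,
        lowpass_order=cfg.detect_lowpass_order,
        ma_window_s=cfg.detect_ma_window_s,
        upper_mult=cfg.detect_upper_mult,
        lower_mult=cfg.detect_lower_mult)
    mask = quality.quality_mask(
        io.EcgSignal(trace.filtered, fs=signal.fs, lead=signal.lead)
        if np.ptp(trace.filtered) > 0 else signal,
        kurtosis_threshold=cfg.quality_kurtosis_threshold,
        sd_multiplier=cfg.quality_sd_multiplier,
        window_s=cfg.quality_window_s,
        min_segment_s=cfg.quality_min_segment_s,
        bridge_s=cfg.quality_bridge_s,
        prefiltered=np.ptp(trace.filtered) > 0)

    beats = detect.modified_pt_detect(
        signal, mask=mask, trace=trace,
        refractory_ms=cfg.detect_refractory_ms,
        gap_mult=cfg.detect_gap_mult,
        median_window_s=cfg.detect_median_window_s)
    if len(beats):
        beats = detect.refine_rpeaks(beats, trace, signal,
                                     radius_ms=cfg.detect_refine_radius_ms)
        if mask.accept.any():
            keep = mask.accept[np.clip(beats.r_indices, 0, mask.accept.size - 1)]
            beats = detect.BeatSet(beats.r_indices[keep], beats.source[keep],
                                   fs=beats.fs, refined=True, note=beats.note)

    report = intervals.IntervalReport()
    selected = None
    ens = None
    if len(beats) >= 2:
        hr, n_hr, valid_hr = intervals.heart_rate(
            beats, tol=cfg.hr_tol, min_beats=cfg.hr_min_beats)
        sd, valid_sd = intervals.sdnn(
            beats, min_beats=cfg.hrv_min_beats,
            reject_outliers=cfg.hrv_reject_outliers, tol=cfg.hr_tol)
        report.hr_bpm, report.n_beats_hr, report.valid_hr = hr, n_hr, valid_hr
        report.sdnn_ms, report.valid_hrv = sd, valid_sd
        report.n_beats_hrv = n_hr

        selected = ensemble.select_beats(
            signal, beats, mask,
            hr_tol=cfg.ensemble_hr_tol,
            rms_lo=cfg.ensemble_rms_lo, rms_hi=cfg.ensemble_rms_hi,
            pre_ms=cfg.ensemble_pre_ms, post_ms=cfg.ensemble_post_ms)
        if len(selected):
            ens = ensemble.ensemble_average(
                signal, selected,
                pre_ms=cfg.ensemble_pre_ms, post_ms=cfg.ensemble_post_ms,
                min_beats=cfg.ensemble_min_beats)
            if fiducials is not None and ens.valid and report.valid_hr:
                rr_s = 60.0 / report.hr_bpm
                qrs, qt, qtc = intervals.cardiac_intervals(fiducials, rr_s)
                report.qrs_ms, report.qt_ms, report.qtc_ms = qrs, qt, qtc
                report.valid_qt = True
    else:
        logger.info("record rejected: %s", beats.note or "fewer than 2 beats")

    return RecordingAnalysis(report=report, mask=mask, beats=beats,
                             selected=selected, ensemble_beat=ens, trace=trace)


def _record_ids(db_dir: Path) -> list[str]:
    return sorted(p.stem for p in db_dir.glob("*.hea"))


def benchmark_database(db_dir: str | Path,
                       window_ms: float = 150.0,
                       algorithm: str = "modified_pt",
                       use_sqi: bool = True,
                       channel: int = 0,
                       config: RunConfig | None = None,
                       beat_codes=io.DEFAULT_BEAT_CODES,
                       ) -> tuple[list[evaluate.BxbResult], evaluate.BxbResult]:
    """Replay the validation protocol over every record in ``db_dir``.

    Returns (per-record results, pooled result).  ``algorithm`` selects
    the modified or the original Pan-Tompkins detector; ``use_sqi``
    disables shutdown gating when False.
    """
    cfg = config or RunConfig()
    db_dir = Path(db_dir)
    ids = _record_ids(db_dir)
    if not ids:
        raise IOError(f"no WFDB records (*.hea) found in {db_dir}")
    results = []
    for rid in ids:
        sig = io.read_record(db_dir / rid, channel=channel)
        ref = io.read_beat_annotations(db_dir / rid, beat_codes=beat_codes)
        trace = detect.preprocess_qrs(
            sig, band_hz=cfg.detect_bandpass_hz,
            band_order=cfg.detect_bandpass_order,
            lowpass_hz=cfg.detect_lowpass_hz,
            lowpass_order=cfg.detect_lowpass_order,
            ma_window_s=cfg.detect_ma_window_s,
            upper_mult=cfg.detect_upper_mult,
            lower_mult=cfg.detect_lower_mult)
        mask = None
        if use_sqi:
            mask = quality.quality_mask(
                io.EcgSignal(trace.filtered, fs=sig.fs), prefiltered=True,
                kurtosis_threshold=cfg.quality_kurtosis_threshold,
                sd_multiplier=cfg.quality_sd_multiplier,
                window_s=cfg.quality_window_s,
                min_segment_s=cfg.quality_min_segment_s,
                bridge_s=cfg.quality_bridge_s)
        if algorithm == "modified_pt":
            beats = detect.modified_pt_detect(
                sig, mask=mask, trace=trace,
                refractory_ms=cfg.detect_refractory_ms,
                gap_mult=cfg.detect_gap_mult,
                median_window_s=cfg.detect_median_window_s)
            if len(beats):
                beats = detect.refine_rpeaks(
                    beats, trace, sig, radius_ms=cfg.detect_refine_radius_ms)
        elif algorithm == "original_pt":
            beats = detect.original_pt_detect(sig)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        res = evaluate.bxb_match(ref, beats, fs=sig.fs, window_ms=window_ms,
                                 mask=mask, record=rid)
        logger.info("%s: Se %.2f%% PPV %.2f%% (%d ref beats)",
                    rid, 100 * res.se, 100 * res.ppv, res.n_ref_beats)
        results.append(res)
    return results, evaluate.pool_results(results)
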