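"""Beat-by-beat scoring against reference annotations, plus the
comparison statistics used to report agreement (Pearson correlation and
Bland-Altman limits).

Matching follows the WFDB ``bxb`` convention: detected and reference
beats are paired one-to-one within an acceptance window (150 ms for
database validation, 100 ms for the stricter protocol).  The matcher is
the symmetric two-pointer maximum-cardinality pairing on the two sorted
beat lists, so swapping the roles of reference and test exactly swaps
false negatives and false positives.  Reference beats that fall inside
quality-rejected ("shutdown") regions and go unmatched are excluded
from the false-negative count rather than penalised; detected beats
inside shutdown regions are removed before matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import BeatSet
from .io import AnnotationSet
from .quality import QualityMask

__all__ = ["BxbResult", "bxb_match", "pool_results", "pearson", "bland_altman"]


@dataclass
class BxbResult:
    """TP/FP/FN tallies for one record or a pooled set."""

    tp: int
    fp: int
    fn: int
    excluded_shutdown: int = 0
    n_ref_beats: int = 0
    sqi_pass: float = 1.0
    n_samples: int = 0          # record length; weights pooled sqi_pass
    record: str = ""

    @property
    def se(self) -> float:
        """Sensitivity TP/(TP+FN): fraction of reference beats found."""
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def ppv(self) -> float:
        """Positive predictive value TP/(TP+FP)."""
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def _max_matching_count(ref: np.ndarray, test: np.ndarray, w: float) -> tuple[int, np.ndarray]:
    """Two-pointer maximum-cardinality matching of two sorted sequences
    under |ref - test| <= w.  Returns (n_matched, matched_ref_flags)."""
    i = j = tp = 0
    matched_ref = np.zeros(ref.size, dtype=bool)
    while i < ref.size and j < test.size:
        if abs(float(ref[i]) - float(test[j])) <= w:
            matched_ref[i] = True
            tp += 1
            i += 1
            j += 1
        elif ref[i] < test[j]:
            i += 1
        else:
            j += 1
    return tp, matched_ref


def bxb_match(ref: AnnotationSet, test: BeatSet, fs: float,
              window_ms: float = 150.0,
              mask: QualityMask | None = None,
              record: str = "") -> BxbResult:
    """Score detected beats against reference annotations.

    Matched pairs are true positives; unmatched detections are false
    positives; unmatched references are false negatives unless they lie
    in a shutdown region, in which case they are excluded.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    window = window_ms / 1000.0 * fs
    ref_idx = np.asarray(ref.indices, dtype=np.int64)
    test_idx = np.asarray(test.r_indices, dtype=np.int64)

    if mask is not None and test_idx.size:
        ok = mask.accept[np.clip(test_idx, 0, mask.accept.size - 1)]
        test_idx = test_idx[ok]

    tp, matched_ref = _max_matching_count(ref_idx, test_idx, window)
    fp = int(test_idx.size) - tp

    unmatched = ref_idx[~matched_ref]
    if mask is not None and unmatched.size:
        in_shutdown = ~mask.accept[np.clip(unmatched, 0, mask.accept.size - 1)]
        excluded = int(in_shutdown.sum())
    else:
        excluded = 0
    fn = int(unmatched.size) - excluded

    sqi = mask.pass_fraction if mask is not None else 1.0
    n_samples = mask.accept.size if mask is not None else 0
    return BxbResult(tp=tp, fp=fp, fn=fn, excluded_shutdown=excluded,
                     n_ref_beats=int(ref_idx.size), sqi_pass=sqi,
                     n_samples=n_samples, record=record)


def pool_results(results: list[BxbResult]) -> BxbResult:
    """Cumulative statistics: counts are summed and Se/PPV recomputed
    from the pooled counts (never averaged); the SQI pass fraction is
    weighted by record length."""
    if not results:
        raise ValueError("pool_results needs a non-empty list")
    tp = sum(r.tp for r in results)
    fp = sum(r.fp for r in results)
    fn = sum(r.fn for r in results)
    exc = sum(r.excluded_shutdown for r in results)
    n_ref = sum(r.n_ref_beats for r in results)
    total = sum(r.n_samples for r in results)
    if total:
        sqi = sum(r.sqi_pass * r.n_samples for r in results) / total
    else:
        sqi = float(np.mean([r.sqi_pass for r in results]))
    return BxbResult(tp=tp, fp=fp, fn=fn, excluded_shutdown=exc,
                     n_ref_beats=n_ref, sqi_pass=sqi, n_samples=total,
                     record="pooled")


def pearson(a, b) -> float:
    """Pearson correlation: covariance over the product of the SDs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("sequences must have equal length")
    if a.size < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def bland_altman(x, y) -> tuple[float, float]:
    """Agreement between two measurement series.

    Returns (bias, loa_half_width): the mean of x - y and 1.96 times
    its sample SD (the half-width of the 95% limits of agreement).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 points")
    d = x - y
    return float(d.mean()), float(1.96 * d.std(ddof=1))
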