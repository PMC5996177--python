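import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noisyecg.detect import BeatSet
from noisyecg.evaluate import bland_altman, bxb_match, pearson, pool_results
from noisyecg.io import AnnotationSet
from noisyecg.quality import QualityMask

FS = 250.0


def _ann(indices):
    return AnnotationSet(np.asarray(indices, dtype=np.int64),
                         ["N"] * len(indices))


def _beats(indices):
    idx = np.asarray(sorted(indices), dtype=np.int64)
    return BeatSet(idx, ["upper"] * idx.size, fs=FS)


def brute_force_max_matching(ref, test, w):
    """Exhaustive maximum one-to-one matching under |r - t| <= w."""
    ref, test = list(ref), list(test)
    if not ref:
        return 0
    best = brute_force_max_matching(ref[1:], test, w)
    for j, t in enumerate(test):
        if abs(ref[0] - t) <= w:
            rest = test[:j] + test[j + 1:]
            best = max(best, 1 + brute_force_max_matching(ref[1:], rest, w))
    return best


# beat trains: strictly increasing, refractory-respecting index lists
def beat_train(max_len=6):
    return st.lists(st.integers(0, 40), min_size=0, max_size=max_len,
                    unique=True).map(
        lambda v: [x * 60 for x in sorted(v)])   # 60 samples > refractory


class TestBxbMatch:
    def test_identical_lists_are_perfect(self):
        idx = [250, 500, 750, 1000]
        res = bxb_match(_ann(idx), _beats(idx), fs=FS)
        assert (res.se, res.ppv) == (1.0, 1.0)
        assert res.fp == res.fn == 0

    def test_acceptance_window_gates_a_120ms_offset(self):
        ref = _ann([1000])
        test = _beats([1000 + int(0.120 * FS)])
        loose = bxb_match(ref, test, fs=FS, window_ms=150.0)
        strict = bxb_match(ref, test, fs=FS, window_ms=100.0)
        assert (loose.tp, loose.fp, loose.fn) == (1, 0, 0)
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)

    def test_shutdown_reference_beat_excluded_not_fn(self):
        accept = np.ones(3000, dtype=bool)
        accept[900:1200] = False
        mask = QualityMask(accept, FS)
        res = bxb_match(_ann([500, 1000, 2000]), _beats([500, 2000]),
                        fs=FS, mask=mask)
        assert res.fn == 0
        assert res.excluded_shutdown == 1
        assert res.tp + res.fn + res.excluded_shutdown == res.n_ref_beats

    def test_detected_beats_in_shutdown_removed_before_matching(self):
        accept = np.ones(3000, dtype=bool)
        accept[900:1200] = False
        mask = QualityMask(accept, FS)
        res = bxb_match(_ann([500, 2000]), _beats([500, 1000, 2000]),
                        fs=FS, mask=mask)
        assert res.fp == 0

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            bxb_match(_ann([100]), _beats([100]), fs=FS, window_ms=0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(ref=beat_train(), test=beat_train(), w_ms=st.sampled_from(
        [50.0, 100.0, 150.0]))
    def test_matches_exhaustive_brute_force(self, ref, test, w_ms):
        if not ref and not test:
            return
        w = w_ms / 1000.0 * FS
        res = bxb_match(_ann(ref) if ref else _ann([]),
                        _beats(test) if test else _beats([]),
                        fs=FS, window_ms=w_ms)
        assert res.tp == brute_force_max_matching(ref, test, w)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(ref=beat_train(), test=beat_train())
    def test_swapping_ref_and_test_swaps_fn_and_fp(self, ref, test):
        if not ref or not test:
            return
        a = bxb_match(_ann(ref), _beats(test), fs=FS)
        b = bxb_match(_ann(test), _beats(ref), fs=FS)
        assert (a.tp, a.fn, a.fp) == (b.tp, b.fp, b.fn)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ref=beat_train(), test=beat_train())
    def test_se_ppv_monotone_in_window(self, ref, test):
        if not ref or not test:
            return
        tps = [bxb_match(_ann(ref), _beats(test), fs=FS, window_ms=w).tp
               for w in (40.0, 100.0, 200.0)]
        assert tps == sorted(tps)


class TestPooling:
    def test_pooling_with_itself_preserves_rates(self):
        r = bxb_match(_ann([250, 500, 750]), _beats([250, 500]), fs=FS)
        pooled = pool_results([r, r])
        assert pooled.se == pytest.approx(r.se)
        assert pooled.ppv == pytest.approx(r.ppv)

    def test_pooled_se_recomputed_from_counts(self):
        from noisyecg.evaluate import BxbResult
        a = BxbResult(tp=99, fp=0, fn=1, n_ref_beats=100)
        b = BxbResult(tp=0, fp=0, fn=1, n_ref_beats=1)
        pooled = pool_results([a, b])
        assert pooled.se == pytest.approx(99 / 101)   # not the mean of rates

    def test_empty_record_changes_nothing(self):
        r = bxb_match(_ann([250, 500]), _beats([250, 500]), fs=FS)
        empty = bxb_match(_ann([]), _beats([]), fs=FS)
        pooled = pool_results([r, empty])
        assert (pooled.tp, pooled.fp, pooled.fn) == (r.tp, r.fp, r.fn)

    def test_count_additivity_vs_concatenated_match(self):
        ref1, test1 = [250, 500, 750], [250, 510, 1100]
        ref2, test2 = [300, 600], [300, 590]
        off = 10_000
        r1 = bxb_match(_ann(ref1), _beats(test1), fs=FS)
        r2 = bxb_match(_ann(ref2), _beats(test2), fs=FS)
        cat = bxb_match(_ann(ref1 + [x + off for x in ref2]),
                        _beats(test1 + [x + off for x in test2]), fs=FS)
        pooled = pool_results([r1, r2])
        assert (pooled.tp, pooled.fp, pooled.fn) == (cat.tp, cat.fp, cat.fn)


class TestStatistics:
    def test_pearson_perfect_and_antiperfect(self):
        a = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson(a, a) == pytest.approx(1.0)
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_pearson_hand_computed_case(self):
        # cov/(sd*sd) for (0,1,2) vs (0,1,4) = 0.9608 by hand
        assert pearson([0, 1, 2], [0, 1, 4]) == pytest.approx(0.9608, abs=2e-4)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [0, 1, 2])

    def test_bland_altman_identical_series(self):
        bias, loa = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, loa) == (0.0, 0.0)

    def test_bland_altman_constant_shift(self):
        x = np.array([1.0, 2.0, 3.0])
        bias, loa = bland_altman(x, x + 5)
        assert bias == pytest.approx(-5.0)
        assert loa == pytest.approx(0.0)

    def test_bland_altman_unit_sd_differences(self):
        # differences (-1, 0, 1): sample SD = 1, half-width 1.96
        bias, loa = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert bias == pytest.approx(0.0)
        assert loa == pytest.approx(1.96)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2, 3])
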