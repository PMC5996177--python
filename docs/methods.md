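# Methods

This note records the model, the tunable parameters, the numerical choices
made where the design was genuinely open, and what the synthetic data do and
do not establish.

## Signal model and scope

The package treats a recording as a uniformly sampled single-lead ECG in
physical units. No resampling is ever applied: all windows and filters are
parameterised in seconds and rendered to samples at the native rate, so the
chain accepts anything from 250 to 1000 Hz (and beyond, within the filter
design limits) unchanged. Multi-lead consensus, beat-type classification,
automated Q/S/T delineation and frequency-domain HRV are out of scope; QRS/QT
measurement takes fiducials placed externally (e.g. by an expert reading the
ensemble beat).

## Signal-quality indices

Both SQIs are computed on the same 5–15 Hz bandpassed trace the detector
uses, over a centred 2-s window at every sample (hop 1):

* **Moving kurtosis**, Pearson convention (fourth central moment over squared
  variance; normal = 3, *not* excess kurtosis — the 3.6 threshold below only
  makes sense in this convention). A clean sinus ECG is dominated by sparse,
  sharp QRS complexes, a strongly leptokurtic waveform (empirically ≈ 10 on
  the bandpassed synthetic signal, > 5 generally); stationary in-band noise
  drags the window statistic toward 3. Windows with `k ≤ 3.6` (default
  `quality.kurtosis_threshold`) are rejected. Windows with zero variance have
  undefined kurtosis and are rejected.
* **Moving SD** flags large-amplitude spikes: windows whose SD exceeds
  `quality.sd_multiplier` (default 1.5) times the whole-record SD are
  rejected. The ratio form makes the mask exactly invariant under amplitude
  scaling, and the kurtosis is shift- and scale-invariant by construction, so
  gain differences between devices do not move the mask.

Implementation: moving moments are computed from cumulative sums of powers
of the (globally mean-removed) signal — O(n), and exactly equal to a naive
two-pass computation per window (tested to 1e-9 relative). Edge windows
shrink down to half length at the record boundaries rather than inventing
data. The whole-record SD for the spike rule is taken on the full filtered
record, before any rejection: a circular definition (SD after rejection)
would make the rule order-dependent for marginal spikes.

Post-processing of the raw accept/reject vector: interior rejected runs
shorter than `quality.bridge_s` (default 0.5 s) are forgiven — isolated
single-window rejections inside otherwise good signal would otherwise
fragment the mask — and accepted runs shorter than `quality.min_segment_s`
(default 2 s) are dropped, since no interval statistic is computable from
under two seconds of signal. Both operations preserve the monotone response
of the mask to its thresholds.

## Detection

The modified Pan–Tompkins chain is causal throughout (its streaming
heritage): first-order Butterworth 5–15 Hz bandpass, the classic five-point
derivative FIR `(fs/8)·[2,1,0,−1,−2]` (exact delay 2 samples), squaring, and
a third-order 8-Hz Butterworth low-pass in place of moving-window
integration, giving one smooth lobe per QRS. Dual thresholds are 1.25× and
0.3× a 5-s trailing moving average of the detection trace, updated at every
sample.

Startup: a trailing average needs history it does not have at the start of a
record. The first second inherits the 1-s expanding-window value; from one
second onward the window expands to 5 s and then slides. A pure expanding
window from the first sample was tried and rejected: its near-zero early
values accept any startup ripple (measured cost ≈ 2–5 percentage points of
Se/PPV on noisy synthetic records).

Candidate peaks are local maxima taken greedily from largest to smallest
with a 200-ms refractory (the cardiac refractory period). Candidates above
the upper threshold are beats. For every inter-beat gap longer than 1.5× the
local median interval (median over beats within 20 s; global median when
fewer than three are available, as at record start), candidates above the
lower threshold are recovered largest-first — but only while the remaining
sub-gap is still implausibly long, and never closer than half the local
median to an existing beat. The proximity guard matters: without it the
largest above-lower-threshold candidate in a long gap is often a T wave
sitting ~300 ms after the last real beat, not the missed beat itself.
Recovery is a single pass; it does not re-trigger on the intervals it
creates beyond the gap being filled.

Beats falling in mask-rejected regions are discarded after detection
(detection runs globally, then masks — the alternative of skipping rejected
regions would perturb filter states at every boundary).

## Refinement

The detection lobe peaks lag the R apex (causal filtering plus smoothing),
so each delineation is refined: within ±150 ms, the two largest local maxima
of the squared derivative bound the QRS upstroke and downstroke; the first
zero-crossing of the derivative between them — located to sub-sample
precision by linear interpolation — is the extremum of the filtered ECG.
Two known delays are then subtracted: the exact 2-sample derivative delay,
and the bandpass residual. The latter is *measured*, not taken from the
filter's nominal group delay: a QRS is wideband relative to a first-order
5–15 Hz filter, and the single-frequency group delay at the band centre
(~32 ms at 1000 Hz) is eight times the actual peak shift of a QRS-width
pulse (~4 ms). The compensation therefore passes a nominal 90-ms Gaussian
QRS template through the designed filter at run time and uses its
sub-sample (parabolically interpolated) peak shift. On clean synthetic
signals the refined index lands within ±2 ms of the true apex at 1000 Hz,
and beat sets rendered at 250/360/1000 Hz agree pairwise within one sample
period of the coarser rate. Windows with fewer than two squared-derivative
maxima keep the original index and log a warning. If refinement ever pulls
two beats inside the refractory, the later one is dropped defensively.

The original 1985 Pan–Tompkins detector (integer-style cascaded filters with
tap spacings scaled from the 200-Hz design, 150-ms moving-window
integration, adaptive signal/noise levels with 1.66·RR search-back) is
included purely as a comparison baseline; published implementation details
are incomplete, so exact parity with historical numbers is not expected.

## Ensemble averaging and intervals

Stacking windows default to 300 ms before and 500 ms after R, fitting the
full QRS–T complex at heart rates up to ~100 bpm. The ±10% heart-rate
criterion is applied on RR intervals (`RR ∈ [median/1.1, median/0.9]`),
equivalent to the HR formulation at this tolerance. Beat RMS is computed
over the stacking window after mean removal so a baseline offset cannot
dominate; the median RR and median RMS are taken over the mask-filtered beat
set. Validity gates mirror the study protocol: 15 beats for HR, 60 for SDNN
and for the ensemble.

SDNN uses the sample SD (n−1), the HRV convention. Because no beat-type
classifier is in scope, "normal-to-normal" is approximated by applying the
same ±60% RR outlier rejection before the SD (`hrv.reject_outliers`,
default on). The RR entering Bazett's correction is the recording's
outlier-rejected median RR — consistent with the per-recording HR.

## Evaluation

Matching is the symmetric two-pointer maximum-cardinality pairing of the two
sorted beat lists under the acceptance window. This reproduces beat-by-beat
(`bxb`) counting semantics, is provably symmetric (swapping reference and
test swaps FN and FP exactly), and equals an exhaustive maximum matcher,
which the test suite verifies by brute force on random small lists. Detected
beats inside shutdown regions are removed before matching (they cannot be
false positives during shutdown); unmatched reference beats inside shutdown
regions are excluded from the FN count rather than penalised, so
`TP + FN + excluded = total reference beats`. Pooled statistics sum counts
first and recompute Se/PPV from the sums; the pooled SQI pass fraction is
weighted by record length. The SQI pass fraction is reported as a fraction
of samples (identical to a fraction of time at uniform fs).

## Synthetic data: what it shows and what it does not

Each synthetic beat is a sum of five Gaussian bumps; centres and widths are
solved so that Q onset = −QRS/2, S end = +QRS/2 and T end = QT − QRS/2
relative to the R apex, giving analytic fiducial and apex ground truth.
Defaults emulate a healthy adult's 150-s resting recording: 75 bpm, 20-ms
SDNN, 90-ms QRS, 400-ms QT, 1-mV R wave. The RR process is i.i.d. truncated
normal — adequate for SDNN, the only HRV statistic in scope, but carrying no
autocorrelation structure. Corruptions: white noise at a requested SNR,
EMG-like bursts (4th-order 5–40 Hz bandpassed noise over a span), 10-ms
impulsive spikes, sinusoidal baseline wander (≤ 0.5 Hz) and mains
interference; every altered span is recorded in the ground truth.

Passing on this generator demonstrates correct mechanics — filter chain,
thresholds, recovery, masking, averaging and interval arithmetic under
controlled noise — but not clinical performance: real dry-electrode
recordings contain nonstationary artifacts, morphology variation, ectopy and
electrode drop-outs that five Gaussian bumps do not produce. The
database-replication tests against the annotated MIT-BIH and European ST-T
databases exist for that purpose and require the user to download those
databases locally.

## Problem sizes and numerical notes

Tests run on 30–240-s synthetic records at 250–1000 Hz, sizes at which every
statistic under test (beat counts, SD of ~200–600 RR intervals, residual
RMS at N ≤ 64) has sampling error comfortably inside the asserted
tolerances. All randomness is seeded; two runs with the same configuration
are byte-identical. Degenerate inputs are defined rather than accidental:
constant signals have undefined kurtosis and are fully rejected; empty masks
yield an empty beat set flagged "no analyzable signal"; fewer than two beats
raises for HR/SDNN; zero-variance sequences raise for Pearson correlation.
Ties in the derivative zero-crossing resolve to the earlier sample.
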