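# Methods

## Input model and quality gating

The unit of input is a per-subject, per-condition RR-interval series: beat
times in ms (cumulative from the first beat), the interval ending at each
beat, and a per-beat normal/non-normal label. Interval *i* (for i ≥ 1) is an
NN interval iff both delimiting beats are labelled normal; the first
interval's opening beat precedes the record, so its status follows beat 0
alone. The NN/RR ratio — the fraction of intervals that are NN — acts as a
signal-quality index: a series is analysed only when the ratio reaches the
threshold (default 0.90, inclusive at the boundary). Gated series have their
non-NN intervals *removed*, never interpolated or corrected; in young healthy
cohorts a low ratio indicates movement artifact, and gating avoids the bias
that correction methods can introduce. Removal leaves gaps in cumulative
time; downstream windowing operates on the original beat times, so gaps
simply contribute no intervals.

## Segmentation

All analysis windows live inside the benchmark 5-min (300 s) excerpt, which
is the first 300 s of the gated NN stream. Windows are defined on cumulative
time, not beat count; an interval belongs to a window when its *ending* beat
time falls in the half-open span [start, end). This convention is
deterministic and makes consecutive windows a strict partition (every
interval in exactly one window). Central windows at scale s occupy
[(300−s)/2, (300+s)/2); consecutive windows tile [k·s, (k+1)·s) with any
trailing remainder discarded. A central window of 300 s is the identity.

## Feature catalogue

23 features in three domains, all computed from the interval list alone.

**Time domain.** MeanNN/StdNN (ms); instantaneous heart rate HRᵢ =
60000/NNᵢ gives MeanHR/StdHR (bpm) — the per-beat transform, not
60000/MeanNN, because the reciprocal is non-linear; RMSSD =
√(mean ΔNN²); NN50 = #{|ΔNN| > 50 ms}; pNN50 = 100·NN50/(N−1). The
variance convention is population (divide by N) everywhere, which makes
SD1 = RMSSD/√2 an exact identity rather than an approximation.

**Frequency domain.** The tachogram (NN vs cumulative time) is resampled at
4 Hz by cubic-spline interpolation, linearly detrended, and fitted with a
Burg autoregressive model of order 16 (statsmodels' Burg estimator; the
order/rate/detrend combination is the common default of short-term HRV
software, and each is configurable). The one-sided PSD is evaluated on a
4096-point grid to 2 Hz. Because an AR spectrum of a near-periodic signal
has poles arbitrarily close to the unit circle, its peaks can be narrower
than any fixed grid; the discretised PSD is therefore rescaled so its
trapezoid integral equals the variance of the detrended signal, which is the
theoretical total power of the model. Band powers integrate the PSD over
LF 0.04–0.15 Hz, HF 0.15–0.4 Hz, total power 0–0.4 Hz (ms²), plus the LF/HF
ratio. Spectral estimates need records at least ten wavelengths of the
band's lower edge: LF, LF/HF and total power require ≥ 120 s; HF ≥ 60 s.

**Non-linear.** Poincaré SD1² = ½·mean(ΔNN²) (dispersion about the identity
line) and SD2² = 2·var(NN) − SD1². Sample entropy (m = 2, r = 0.2·SD,
Chebyshev distance, self-matches excluded, both template lengths counted
over the first N−m templates) and approximate entropy (same parameters,
self-matches included); ApEn is unreliable below 180 s and is masked there.
DFA integrates the mean-centred series and fits log F(n) vs log n by least
squares over boxes 4–16 (α1) and 16–64 (α2) with non-overlapping linear
detrending per box. The correlation dimension D2 is the Grassberger–
Procaccia slope of log C(r) vs log r at embedding dimension 10, delay 1,
Euclidean norm, over an automatically selected scaling region (grid points
where C(r) lies in [1 %, 20 %] of pairs, widened to 50 % if too narrow;
fewer than four usable points flags the feature non-computable).
Recurrence quantification uses the same embedding with radius r = √m·SD:
REC is the % of recurrent point pairs (line of identity excluded);
diagonal lines of length ≥ 2 give the mean (RPlmean) and maximum (RPlmax)
length, determinism (RPadet, % of recurrent points on such lines) and the
Shannon entropy of the line-length distribution (ShanEn, nats by default;
bits available).

**Computability mask.** 300 s and 180 s: all 23; 120 s: ApEn masked (22);
60 s: LF, LF/HF, total power and ApEn masked (19); 30 s: only the seven
time-domain features plus SD1/SD2 (9). Masked features serialise as explicit
nulls with a false computability flag — never silent zeros. A feature the
mask allows can still come back non-computable on a degenerate excerpt
(e.g. D2 on a constant series).

## Surrogate gate

For each feature and scale, the paired rest-vs-stress contrast over subjects
is tested with a two-sided Wilcoxon signed-rank test: zero differences are
dropped; with n ≤ 15 remaining pairs the exact null distribution is
enumerated over all 2ⁿ sign assignments (valid under rank ties); above that
a normal approximation with continuity and tie corrections is used. The
trend code combines significance (p < 0.05) with the direction of the median
change (exact median ties encode as a non-significant increase, a documented
convention). Spearman correlations between each ultra-short feature and its
5-min equivalent are computed per phase with average ranks for ties.

A scale is retained when at least `min_pass = 3` features individually meet
both gate criteria there; with the shipped evidence tables this retains
{180, 120, 60} s and drops 30 s. A feature passes the gate when its trend is
significant at the benchmark and significant with the same direction at
every retained scale, and ρ > 0.7 with p_ρ < 0.05 at every retained scale in
both phases. "Same behaviour" is operationalised as *significant and
co-directional*, the conjunction of the two stated requirements. Bland–
Altman bias (median difference, 5-min minus ultra-short) and 95 % limits of
agreement (mean ± 1.96·sample SD) are reported but advisory. No multiple-
testing correction is applied by default (matching the workflow the gate
formalises); Benjamini–Hochberg is available behind a flag.

The two evidence tables shipped in `uhrv/data/` are transcriptions of
published trend codes and correlation coefficients; two typographically
ambiguous cells in the flattened source were resolved against the
publication's own per-scale significance tallies, as noted in the file
headers.

## Classification harness

Subjects are split 60/40 into folder 1 (selection, training, validation) and
folder 2 (testing), both conditions of a subject co-located — validation is
person-independent throughout, including the 3-fold cross-validation folds,
which partition subjects, never instances. Feature selection on folder-1
5-min features: relevance by paired Wilcoxon (p < 0.05), then redundancy by
clustering features whose within-condition |ρ| exceeds 0.7 (averaged over
rest and stress — pooling conditions would let the stress shift itself link
unrelated features) and keeping the lowest-p representative per connected
component.

The model grid spans kNN (k ∈ {1,3,5}), LDA, an entropy-criterion decision
tree (min-leaf ∈ {2,5,10,20} × cost-complexity pruning α ∈ {0, 0.01, 0.02};
this CART configuration stands in for C4.5-style gain-ratio splitting with
confidence-factor pruning, for which no Python implementation is standard),
a polynomial-kernel SVM (degree 1–5) and a single-hidden-layer (3-unit)
perceptron (SGD, learning rate ∈ {0.3, 0.6, 0.9}, momentum ∈ {0.2, 0.6,
1.0}). Every fit z-scores features with training-fold statistics (kNN, SVM,
LDA and the MLP are scale-sensitive). The winner is the highest mean CV AUC,
ties broken by accuracy then by the simpler model (family rank, then smaller
hyperparameters). Scores are stress-class probabilities for kNN/tree/MLP
(threshold 0.5) and discriminant values for LDA/SVM (threshold 0); stress is
the positive class; AUC is the rank statistic and is invariant under
monotone score transforms. The selected model is trained once on folder-1
5-min features, frozen, and assessed on folder-2 features at each scale and
on consecutive 1-min windows (per-window metrics plus mean ± SD).

## Synthetic cohort generator

Each series is a sinusoid-plus-noise tachogram: RRᵢ = μ + A_LF·sin(2π·0.10
tᵢ + φ_LF) + A_HF·sin(2π·0.25 tᵢ + φ_HF) + εᵢ, ε ~ N(0, σ²), with tᵢ the
cumulative beat time and phases drawn per series. This gives analytic
control: MeanNN ≈ μ, a pure tone of amplitude A carries A²/2 ms² in its
band, StdNN² ≈ A_LF²/2 + A_HF²/2 + σ². Defaults (rest: μ = 850 ms, A_LF =
30, A_HF = 40, σ = 25; stress: μ = 700, A_LF = 22, A_HF = 18, σ = 24;
between-subject SDs 60/6/10/5 ms; duration 330 s so a full 300-s excerpt
survives trimming; 42 subjects) encode the stress contrast the workflow is
designed to detect: shorter MeanNN, lower StdNN and HF power, and — because
the 60000/NN transform amplifies variability at short NN — higher MeanHR
and StdHR despite the lower StdNN. A shared per-subject offset vector ties
the rest and stress draws, so the paired contrast is consistent within
subjects. Ectopic-beat artifacts are emulated by relabelling random beats
non-normal and shifting them 40 % early (a short–long couplet that preserves
cumulative time), which exercises the NN/RR gate: the both-ends-N rule makes
the affected interval fraction ≈ twice the beat rate, so ~3 % ectopy passes
the 90 % gate and ~20 % fails it.

What the generator does *not* emulate: respiratory frequency variation and
sinus-arrhythmia nonstationarity, circadian and posture effects, true
non-linear heartbeat dynamics (its attractor is a torus plus noise), and
realistic ectopic morphology. Tests passing on this cohort therefore show
the pipeline's statistical machinery is correct and calibrated — not that
any particular feature is a valid surrogate in clinical data.

## Numerical choices and scale of the shipped analyses

Cubic resampling needs ≥ 4 intervals; Burg needs order+1 points. Constant
tachograms yield an identically-zero spectrum rather than an AR fit.
Degenerate entropies (zero match counts) and D2 without a scaling region are
flagged non-computable. Wilcoxon warns and returns p = 1 when every paired
difference is zero.

The test suite and the acceptance script run the end-to-end analyses on a
40-subject synthetic cohort at scales {300, 180, 120, 60} s, a 200-seed
zero-contrast null calibration of the trend test using the five continuous
time-domain features, and 50-seed DFA calibrations — sizes chosen so the
whole analysis reruns in about a minute while keeping Monte-Carlo error well
inside the asserted bands. Known limitations: DFA α1 on white noise is
biased slightly above 0.5 at n = 300 with box sizes 4–16 (a finite-size
property of the estimator, visible in the calibration outputs); the AR
band powers inherit cubic-spline smoothing, which attenuates power near the
Nyquist edge of the HF band by a few percent; and the D2 scaling-region
heuristic targets clean low-dimensional signals — on short noisy excerpts
it measures an effective, not asymptotic, dimension.
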