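# Methods

This note documents the models, conventions and numerical choices
behind `respiro`, and what the synthetic validation does and does not
demonstrate about real respiratory data.

## Signal model and IBI extraction

A respiratory airflow record is treated as a uniformly sampled
single-channel waveform (`Waveform`: start time, sampling rate fs,
amplitudes). Files are plain delimited text with a header; the
delimiter is auto-detected among comma/tab/semicolon. When a time
column is present, fs is inferred from the median step and the series
is rejected if any step deviates more than 1% from it. Resampling
(e.g. 250 → 50 Hz) uses linear interpolation onto the new uniform grid:
deterministic, exact for constants, and adequate for respiratory
dynamics whose energy sits far below the Nyquist rate at either
frequency; band-limited interpolation is a documented divergence
candidate for signals with substantial high-frequency content.

Breath peaks are found in two stages:

1. **Candidacy** on a denoised copy — centered moving average (default
   0.5 s, truncated at the record edges) or zero-phase 4th-order
   Butterworth low-pass (default cutoff 1 Hz) — keeping strict local
   maxima that are maximal within ±`min_distance_s` (default 1.0 s,
   since >60 breaths/min is implausible at rest; ties go to the
   earliest sample). This window-maximum rule, rather than iterative
   neighbor pruning, is what removes noise bumps in the inter-breath
   troughs. Candidates within the smoothing edge margin (half the
   moving-average window, or half a cutoff period for the filter) of
   the record boundaries are dropped because the smoothed values there
   are unreliable.
2. **Reporting**: the peak position is the smoothed-signal maximum and
   the height is the raw amplitude at that sample. An optional
   `refine_raw` mode instead moves the position to the raw-signal
   argmax within ±`min_distance_s`/2. It is off by default: on a
   nearly flat pulse apex with noise at ~10% of amplitude the raw
   argmax is close to uniformly distributed over the refinement
   window, which empirically caps the fraction of peaks localized to
   within 0.2 s at about 70% however the signal is smoothed, while the
   smoothed maximum localizes >99% of peaks. Raw refinement is useful
   when exact raw peak heights matter more than timing.

The IBI series is the successive difference of peak times, stamped at
the later peak of each pair. For the 4 s breaths used in validation a
1.0 s moving-average window (a quarter cycle) is the analysis choice;
0.5 s remains the package default for general use.

## Multiscale sample entropy

SampEn(m, r) counts unordered template pairs i < j with both template
sets indexed 1..N−m, excluding self-matches, under the Chebyshev
distance — the convention of the classic PhysioNet C implementation
this measure descends from. B counts length-m matches, A length-(m+1);
SampEn = −ln(A/B). A = 0 or B = 0 makes the entropy undefined; this is
raised as a distinct condition and reported as a missing value in
tables, never silently as 0 or ∞.

Coarse-graining takes non-overlapping block means of length τ, dropping
the remainder. The tolerance r = r_coef × SD(original series) (sample
SD, n−1 denominator) is fixed once and reused at every scale, so the
entropy decline with τ reflects the loss of fast variability, not a
rescaled yardstick; a per-scale-r variant is available behind a flag.
Defaults m = 2, r_coef = 0.15, τ_max = 10. Pair counting is a chunked
vectorized O(N²) pass, exact (integer counts) and matched against an
explicit-loop oracle in the tests.

## lowPSD

The preprocessing chain is mean subtraction, multiplication by the
parabolic window w_j = 1 − (2j/(N+1) − 1)², then bridge detrending
(subtracting the line through the first and last samples), each step
independently switchable. The raw periodogram is normalized so that
the two-sided total equals the mean square of the input (checked as a
Parseval identity in the tests). The spectral exponent β is minus the
OLS slope of log₁₀ power on log₁₀ frequency over the lowest ⅛ of the
positive frequency range (flag-adjustable); the intercept, fit bounds
and R² are reported so the fitted line can be regenerated exactly from
the outputs. For IBI input the sampling interval defaults to the mean
IBI so frequencies read in Hz; a per-interval (dt = 1) mode exists
because the axis convention for unevenly generated interval series is
ultimately a choice.

## MFDFA

Standard pipeline: profile (cumulative sum of the mean-subtracted
series); segmentation into ⌊N/s⌋ windows from the start **and** the end
(2N_s total, so no tail is discarded); per-window least-squares
polynomial detrending (default order 1) via one shared Vandermonde
solve per scale; moment averaging

    F_q(s) = {(1/2N_s) Σ [F²]^{q/2}}^{1/q},  F_0(s) = exp{(1/4N_s) Σ ln F²},

computed in log space (logsumexp) so large negative q do not underflow.
h(q) is the log₂–log₂ OLS slope of F_q(s) over the fit range (default:
all scales), with per-q R² recorded. τ(q) = q·h(q) − 1 (τ(0) = −1
identically) and the singularity spectrum comes from central finite
differences on the interior of the q grid — one-sided endpoint
estimates are deliberately not reported. Defaults: q ∈ {−10,…,10}
(q = 0 included via the log-average), ~20 log-spaced scales from 16 to
N/10. Records too short for that grid fall back to poly_order+2 .. N/4
so short clinical segments still produce a fit. Segments whose
detrending residual is at floating-point rounding level (relative
threshold 10⁻²² of the profile's mean square) raise a degenerate-signal
error rather than polluting the moments. Estimated h(2) below 0.1
raises an error pointing to the sign-modified MFDFA variant for
anti-persistent/negative-exponent signals, which is outside this
package's scope.

For the dyadic cascade test signal (length 2¹⁶) the validation uses
dyadic scales 2⁴..2¹²: windows aligned with the cascade's self-similar
structure avoid the segmentation artifacts non-dyadic windows introduce
on that particular signal (max |h(q) − closed form| drops from ~0.07 to
~0.016). Real data have no preferred scale grid and use the default.

## Extended BMF model fit

h(q) = 1/q − ln(αᵠ + βᵠ)/(q ln 2) with the removable singularity at
q = 0 filled by its analytic limit −(ln α + ln β)/(2 ln 2), so q = 0 is
never excluded from the fit. The least-squares fit runs on
logit-transformed parameters (bounds handled smoothly, clipped at
|logit| ≤ 30 to stay strictly inside (0,1) in floats) from five
deterministic starts that straddle the α↔β symmetry, including the
monofractal point α = β = ½; parameters are ordered β ≤ α afterwards
so h_max ≥ h_min. Equal weights per q by default, optional per-q
weights. Goodness of fit is the Pearson correlation between observed
and predicted h(q) (defined as 1 for an exact constant fit), with RMSE
reported alongside as a clearly separate diagnostic. Derived exponents:
h_min = −ln α/ln 2, h_max = −ln β/ln 2, Δh = h_max − h_min. Note the
convergence h(q) → h_min/h_max is only O(1/q), so finite-q curves sit
visibly above/below the limits (at q = 10, by about 0.1).

## Group statistics

Per group: n, mean, sample SD (n−1), SE, median, and a Student-t
confidence interval (95% default — cohort sizes in this domain are
~19/group, too small for the normal approximation); single-value groups
report missing dispersion rather than erroring. The one-way ANOVA
decomposition (SSB/SSW, df k−1 and n−k) is computed explicitly so
degenerate inputs are well defined: all values identical → F = 0,
p = 1; zero within-group variance with unequal means → F = ∞ with the
smallest positive representable p. The p-value uses the F survival
function; with two groups F equals the pooled t², which the tests use
as an independent oracle. No multiplicity adjustment is applied across
features or q values.

## Synthetic generators

* **Binomial cascade** (deterministic p-model): element i of 2ⁿ has
  value a^{ones(i)}(1−a)^{n−ones(i)} with ones(i) the 1-bit count of
  the 0-based index; the series sums to 1 and its h(q) has the same
  closed form as the BMF model with (α, β) = (max(a,1−a), min(a,1−a)).
  The a ↔ 1−a series are permutations of each other.
* **Fractional Gaussian noise** by circulant embedding of the exact
  autocovariance γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); a
  non-positive-definite embedding (rare at small n) is retried with the
  embedding doubled. Exact target covariance makes fGn a trustworthy
  oracle for h(2) = H and β = 2H − 1.
* **Simulated respiration**: cycle durations drawn from a normal
  truncated below at mean − 2·SD (SD = 0 gives the exact deterministic
  limit), each cycle a raised-cosine pulse peaking at its midpoint,
  plus white Gaussian noise. The truth records exact apex times on the
  continuous axis. Validation conditions: 10 minutes at 50 Hz, IBI
  4 ± 0.3 s, noise 10% of amplitude.

All generators are pure functions of their arguments including the
seed.

What these fixtures do **not** emulate: baseline drift, movement
artifacts, apneas, amplitude variation across breaths, and the
long-range correlation structure of real IBI series (simulated cycle
durations are independent draws). Passing validation therefore
demonstrates correctness of the estimators on signals with known
ground truth, not clinical performance on noisy recordings; the
subject-exclusion step real studies apply ("excessive false signals")
is not operationalized here.

## Problem sizes used in validation

Monte-Carlo checks use fGn of length 2¹⁴ over 10 seeds, the 16-level
cascade (2¹⁶ samples), white-noise MSE at N = 6000 over 3 seeds, 10
simulated 10-minute respiration records, 200 random series against the
sample-entropy counting oracle and a randomized N ≤ 64 suite against
the loop-level MFDFA oracle. These sizes give standard errors well
inside the asserted tolerances while keeping the whole suite fast.

## Known limitations

* Standard MFDFA only; series with h(2) < 0.1 need the sign-modified
  variant and are rejected with a pointed error.
* No WFDB/EDF binary readers; delimited text only.
* lowPSD applies to one series at a time; no Welch averaging or
  multitaper option.
* The optimizer reports `converged=false` with best-so-far parameters
  rather than raising, so downstream tables always fill.
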