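# respiro

Complexity and fractality analysis of continuously monitored respiratory
signals (CMRS).

Airflow recorded at the mouth or nose is one breathing waveform after
another. The physiologically interesting structure is not in the raw
trace but in the **inter-breath interval (IBI)** series — the times
between successive breath-cycle peaks — which in healthy subjects shows
long-range correlations and multifractality that change with age and
disease. `respiro` extracts the IBI series from a raw waveform and
quantifies it three ways:

* **Multiscale sample entropy (MSE).** Sample entropy
  SampEn(m, r) = −ln(A/B), the negative log conditional probability that
  templates matching for m points (within Chebyshev tolerance r) still
  match for m+1, computed on coarse-grained (block-averaged) copies of
  the series at scales τ = 1..τ_max. The tolerance r is fixed from the
  SD of the original series and held across scales.
* **lowPSD spectral exponent.** After mean removal, parabolic-window
  tapering and bridge detrending, the periodogram's log–log slope is
  fitted over the lowest ⅛ of the frequency range; the spectral exponent
  is β = −slope (for fractional Gaussian noise, β = 2H − 1).
* **Multifractal detrended fluctuation analysis (MFDFA).** The
  q-order fluctuation function F_q(s) of the integrated, segment-wise
  polynomially detrended series yields the generalized Hurst exponent
  h(q) (slope of log₂F_q vs log₂s), the mass exponent τ(q) = q·h(q) − 1
  and the singularity spectrum (α, f(α)) by Legendre transform. An
  **extended binomial multifractal (BMF) model**

      h(q) = 1/q − ln(αᵠ + βᵠ)/(q ln 2),   0 < β ≤ α < 1

  is fitted to h(q) by nonlinear least squares, giving
  h_min = −ln α/ln 2, h_max = −ln β/ln 2 and the multifractal width
  Δh = h_max − h_min.

Group-level summaries (n, mean, SD, SE, median, t-based CI) with one-way
ANOVA support cohort comparisons of any extracted feature. Synthetic
generators with exact ground truth (binomial cascade, fractional
Gaussian noise via circulant embedding, simulated breathing) make every
stage verifiable without external data.

## Worked example

Simulate five minutes of breathing (mean IBI 4 s, SD 0.3 s, 10%
additive noise) and run the whole pipeline:

```sh
respiro simulate resp --duration 300 --fs 50 --seed 1 --out w.csv
respiro pipeline --in w.csv --out run1/ --window-s 1.0
cat run1/bmf.json
```

```json
{
  "alpha": 0.7897348068041599,
  "beta": 0.38665096326748016,
  "converged": true,
  "delta_h": 1.0303364699116961,
  "goodness": 0.9763489595438096,
  "h_max": 1.3708962876343005,
  "h_min": 0.3405598177226044,
  "rmse": 0.06918590932489349
}
```

`run1/` also contains `ibi.csv` (peak time + interval), `mse.csv`
(SampEn per scale), `psd.csv` + `psd.fit.json` (periodogram and the
low-frequency β fit), and `mfdfa/` with `fq.csv`, `hq.csv`, `tauq.csv`
and `spectrum.csv`. Here the simulated IBIs are independent draws, so
the estimated h(2) ≈ 0.5 and the apparent width Δh ≈ 1.0 reflects
finite-size scatter of a short (~73-interval) series, not genuine
multifractality — the goodness 0.976 is the Pearson correlation between
observed and model h(q). Real 2-hour records give ~1800 intervals and
much tighter fits.

The same operations are available as a library
(`respiro.find_peaks`, `respiro.mse`, `respiro.low_psd`,
`respiro.mfdfa`, `respiro.fit_bmf`, `respiro.group_summary`, ...); every
CLI run writes a JSON copy of its resolved parameters next to its
outputs and is byte-reproducible for a fixed seed.

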