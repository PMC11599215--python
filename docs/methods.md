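# Methods

## Estimators

**DCCC at one scale.** The two equal-length signals are cut into
N = ⌊L/s⌋ consecutive non-overlapping windows of length *s*, starting at
sample 0; the trailing remainder is discarded (the standard detrended
cross-correlation convention). Each window is detrended by a least-squares
polynomial of degree *p* (default 2) against the sample index, and the
coefficient is the window-averaged covariance over the geometric mean of the
window-averaged variances. Variances and covariances use the population
divisor *s* uniformly; the ratio is invariant to the divisor convention as
long as numerator and denominator use the same one, which is the contract
the tests pin down. The result is in [−1, 1] by Cauchy–Schwarz. A signal
whose detrended windows are all exactly zero has no defined coefficient and
raises a degenerate-signal error.

**Scales from frequencies.** Analysis frequencies f_min..f_max (step
f_step) are converted to integer scales s = round(SR/f). The grid requires
f_max below Nyquist and every window to hold at least 8 samples; at
estimation time, frequencies whose scale exceeds the signal length or falls
below p + 2 are dropped with a logged count and the remaining weights are
renormalized. Frequencies that round to the same integer scale share one
DCCC computation but keep their individual spectral weights. A single
window (N = 1) is permitted — this is the operating point of slow bands on
short recordings.

**Spectral weights.** Both signals are detrended as a whole (same degree),
and the one-sided cross-periodogram is computed from the FFT of the full
signals. Each requested frequency reads the magnitude of its nearest
spectral bin; weights are these magnitudes normalized to sum to one over
the retained frequencies. The magnitude is assembled from explicitly
symmetric real/imaginary parts so that the weights — and hence MDC₃ — are
bitwise identical under exchange of the two signals. Welch averaging of the
cross-spectral density is available as an option (`welch_nperseg`) for
noisy spectra; the default is the plain whole-signal periodogram, the
simplest estimator consistent with the weighting's definition. If the
cross-spectrum is identically zero at every retained bin (orthogonal pure
tones), weights fall back to uniform.

**Fisher-z combination.** Per-scale coefficients are clipped to
±(1 − 10⁻¹²) before atanh so the transform stays finite (self-coupling is
the case that needs it), averaged with the spectral weights, and mapped
back with tanh. When every scale carries the same coefficient c the result
is c exactly (weights sum to one); this identity is tested.

**Directed variant.** Within each window, the covariance numerator is
replaced by the signed lagged covariance with the largest absolute value,
scanned separately over negative lags (first signal leading) and positive
lags (lagging). A lag k pairs x̂[t+k] with ŷ[t]; the divisor is the overlap
length, lags with fewer than 2 overlapping samples are excluded, and ties
in |cov| resolve to the smaller |lag|, then the negative lag. Lag 0 belongs
to neither direction, so leading and lagging partition the lag set. The
variance normalization and spectral weighting are unchanged — the minimal
substitution into the undirected pipeline. Because the lag set of
(y, x, positive lags) mirrors (x, y, negative lags), the identity
`dmdc3(x, y).leading == dmdc3(y, x).lagging` holds to machine precision.
Two open readings were settled as follows: the lag span "signal length" is
interpreted as the *window* length, since the shift applies to a windowed
quantity; and the sign of the maximal-|·| covariance is kept (anticorrelated
driving is meaningful downstream), not its absolute value.

The per-direction ratios are not algebraically confined to [−1, 1] — a
max-|·| over inflated small-overlap lags can exceed the pooled variance —
so they are clipped like DCCC before atanh. On heavily low-pass-filtered
signals many scales can saturate the clip, which makes the directed
estimate coarse; this is inherent to the max-|lagged cov| definition and is
the main caveat for strongly smoothed data.

**Baselines.** Pearson's r is the plain product-moment correlation of the
raw signals. The lagged-covariance baseline (LG) applies the directed lag
scan to the *whole*, globally detrended signal as a single window, without
variance normalization; it is Z-scored at the matrix level before
comparisons. Signals are never cumulatively summed before estimation;
integration adds non-stationarity and demonstrably degrades the detrended
estimators, and the `integrate` flag exists only to reproduce that
comparison.

## Ground-truth simulator

Coupled ARFIMA(0, d, 0) pairs are truncated moving averages
A_t = Σₙ₌₀¹⁰⁰ αₙ(d) ε_{A,t−n} with αₙ(d) = Γ(n+d)/(Γ(n+1)Γ(d)) evaluated in
log-gamma space (overflow-safe to d = 1.4, n = 100). The second channel
shares innovations ε_B = ρ ε_A + ε √(1−ρ²), so the pair carries innovation
correlation ρ exactly; because both channels use the same kernel, the
signal-level correlation is also ρ. Per pair, length + 101 innovations are
drawn (ε_A first, then ε, from a single seeded generator) so every output
sample has a complete kernel history. Two regimes bundle downstream
defaults: `eeg_meg` (SR 250 Hz, band 0.5–31 Hz step 0.5) and `fmri`
(SR 1 Hz, band 0.01–0.12 Hz step 0.01); both bands keep at least 8 samples
per window. Note the 100-term truncation makes even d ≥ 0.5 processes
technically finite-variance: sample variance grows over roughly the kernel
span and then saturates, which is sufficient to produce the non-stationary
behavior of interest at the lengths studied.

`simulate_delayed_pair` shifts the coupled innovation component by an
integer delay, giving a directed (effective) connection with known lag —
the ground truth for the directed benchmark.

What the generator does *not* emulate: oscillatory spectra, hemodynamic or
measurement filtering, non-Gaussian amplitude distributions, volume
conduction, and nonstationarity of the coupling itself. Passing benchmarks
on this ground truth demonstrates estimator calibration and robustness to
fractional-integration nonstationarity, not performance on any particular
recording modality.

## Benchmarks and statistics

The undirected benchmark simulates, for every (d, length, ρ) cell, a set of
replicate pairs, applies each estimator and takes the RMSE against ρ. This
gives, per (estimator, d, length), an RMSE vector over the ρ grid; the two
estimators' vectors are compared with a paired test gated on normality:
both RMSE distributions must pass a Lilliefors test (statsmodels table
approximation) at α = 0.05 for the paired t-test to be used, otherwise the
Wilcoxon signed-rank test (zero differences dropped; identical vectors
report p = 1). The gate is applied to the two distributions themselves
rather than to their paired differences — the defensible alternative — and
is flagged here because either reading is possible. Per-d p-values are
Benjamini–Hochberg-adjusted within each signal length. Default replicate
count is 100 per cell (the test suite uses 50–100); ρ grid
−0.9..0.9 step 0.1, d grid and lengths configurable. All replicate seeds
spawn deterministically from one master seed; identical configurations
reproduce identical reports.

The directed benchmark builds a 4-channel network with two known delayed
couplings (0→1 with ρ = 0.8, delay 1 sample; 2→3 with ρ = −0.6, delay 2
samples; remaining channels independent) in the fMRI regime with d = 0.3 —
the stationarity level that matches the long-memory character reported for
BOLD signals (Hurst exponent near 0.8). Directed matrices are estimated
with dMDC₃ and LG, Z-scored over the off-diagonal entries, and compared by
RMSE to the Z-scored ground-truth matrix, as a function of signal length.
A structural caveat: LG's max-|cov| scan over lags up to ±(L−1) is
dominated by the constant number of minimal-overlap lags, whose noise
amplitude does not depend on L, so its Z-scored accuracy is largely flat in
length rather than strictly deteriorating; the windowed dMDC₃, whose lag
range is fixed by the scale rather than the recording length, gains
steadily from longer recordings.

Matrix Z-scoring standardizes over the included entries (diagonal excluded
by default and left untouched); node strength sums *signed* incident
weights (anticorrelations subtract; an absolute-value option exists),
excluding the diagonal, and adds in- and out-strength for directed
matrices. Matrix averaging across segments or sessions is entrywise
Fisher-z: clip, atanh, mean, tanh.

## Numerical conventions and edge cases

- Windows and segments start at sample 0; remainders are discarded.
- Fisher clipping bound 10⁻¹² inside ±1, everywhere atanh is applied.
- Nearest-bin lookup uses argmin of the absolute frequency difference
  (first bin wins exact ties).
- Text output uses 17 significant digits, so write→read round-trips are
  exact for doubles.
- Polynomial detrending solves a pseudoinverse on an index scaled to [0, 1]
  for conditioning; windows must hold at least degree + 2 samples.

## Problem sizes

The test suite validates oracle equivalence on pairs up to 1000 samples,
stationary recovery at 10 000 samples × 200 replicates, the
non-stationarity benchmark at 5000 samples × 100 replicates over the full
ρ grid with d ∈ {0.1, 0.9, 1.1, 1.4}, and the directed benchmark at
lengths 100–500 × 100 replicates. The acceptance script uses 50–100
replicates per quantity. These sizes give Monte-Carlo error comfortably
below the asserted tolerances (e.g. mean-recovery tolerance ±0.03 against a
standard error near 0.005).
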