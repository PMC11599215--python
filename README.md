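# mdc3

Coupling estimation for non-stationary signals: the **multiscale detrended
cross-correlation coefficient** (MDC₃), its directed variant (dMDC₃),
baseline estimators, a coupled-ARFIMA ground-truth simulator, and a
benchmark harness.

## Why

Functional connectivity studies routinely quantify the coupling of two
neurophysiological time series with Pearson's correlation *r*ₚ. Most
biosignals (EEG, MEG, BOLD fMRI), however, are non-stationary: their mean,
variance and covariance drift over time, which biases *r*ₚ. The detrended
cross-correlation coefficient (DCCC) counters this by working on
polynomially detrended windows of length *s* (the *scale*):

```
DCCC(s) = mean_i cov(X̂ᵢ, Ŷᵢ) / sqrt( mean_i var(X̂ᵢ) · mean_i var(Ŷᵢ) )
```

where X̂ᵢ, Ŷᵢ are the detrended contents of the *i*-th non-overlapping
window. DCCC depends on the arbitrary choice of *s*. MDC₃ removes that
dependence: the user chooses analysis *frequencies* f, each mapped to a
scale s = round(SR/f) through the sampling rate SR, and the per-scale
values are combined as a Fisher-z weighted average,

```
MDC₃ = tanh( Σ_s  w_s · atanh(DCCC(s)) )
```

with weights w_s given by the relative magnitude of the cross-spectral
density of the (globally detrended) pair at the corresponding frequency.
The result lies in (−1, 1) and reads like a correlation.

The directed variant dMDC₃ replaces each window's covariance with the
signed maximum-absolute *lagged* covariance, evaluated separately over
negative lags (first signal leading) and positive lags (first signal
lagging), yielding a (leading, lagging) pair that serves as a proxy for
effective connectivity.

For validation the package simulates coupled ARFIMA(0, d, 0) pairs: moving
averages of Gaussian innovations with kernel αₙ(d) = Γ(n+d)/(Γ(n+1)Γ(d))
truncated at 100 terms, where the innovations of the second channel are
ε_B = ρ·ε_A + ε·√(1−ρ²), so the pair has known coupling ρ while d dials
the non-stationarity (d < 0.5 stationary, d ≥ 0.5 non-stationary).

## Worked example

Simulate one strongly non-stationary pair (d = 1.1) with known coupling
ρ = 0.5 and estimate it with MDC₃ and with Pearson's r:

```bash
mdc3 simulate --d 1.1 --rho 0.5 --length 5000 --seed 42 --out simdir
mdc3 estimate --input simdir/pair_0000.csv --sr 250 \
    --fmin 0.5 --fmax 31 --fstep 0.5
mdc3 estimate --input simdir/pair_0000.csv --sr 250 \
    --fmin 0.5 --fmax 31 --fstep 0.5 --estimator pearson
```

prints (abridged)

```
{"estimator": "mdc3",    "value": 0.6033588105514334, ...}
{"estimator": "pearson", "value": 0.6339382837100237, ...}
```

Both estimates err above the true ρ = 0.5 on this single noisy draw, but
MDC₃ is closer; over many replicates its RMSE against ρ is roughly 25%
lower than Pearson's at this non-stationarity level (see below), while the
two are indistinguishable for stationary signals.

The same functionality is available as a library:

```python
import numpy as np
from mdc3 import ARFIMAConfig, simulate_pair, mdc3, pearson_r

cfg = ARFIMAConfig(d=1.1, rho=0.5, length=5000, seed=42)
a, b = simulate_pair(cfg)
print(mdc3(a, b, cfg.frequency_grid()).value, pearson_r(a, b))
```

Multichannel recordings are handled by `mdc3 network` (or
`mdc3.fc_matrix`), which builds a labeled connectivity matrix with any
estimator and computes signed node strengths, with optional segmenting and
Fisher-z averaging of matrices across segments or sessions.

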