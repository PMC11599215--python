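"""Independent brute-force reference implementations used only by tests.

Everything here is written as explicit loops and direct formulas (normal
equations, manual FFT periodogram, exhaustive lag scans) so it shares no code
path with the package implementation it checks.
"""

import numpy as np


def brute_polyfit_residuals(segment, degree):
    """Residuals of a polynomial fit solved via the normal equations."""
    seg = np.asarray(segment, dtype=float)
    s = len(seg)
    t = np.arange(s) / max(s - 1, 1)
    design = np.empty((s, degree + 1))
    for j in range(degree + 1):
        design[:, j] = t ** j
    coef = np.linalg.solve(design.T @ design, design.T @ seg)
    fitted = design @ coef
    return seg - fitted


def brute_dccc(x, y, s, degree):
    """Explicit per-window transcription of the DCCC definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_win = len(x) // s
    covs, vxs, vys = [], [], []
    for i in range(n_win):
        xw = brute_polyfit_residuals(x[i * s:(i + 1) * s], degree)
        yw = brute_polyfit_residuals(y[i * s:(i + 1) * s], degree)
        covs.append(sum(a * b for a, b in zip(xw, yw)) / s)
        vxs.append(sum(a * a for a in xw) / s)
        vys.append(sum(b * b for b in yw) / s)
    return (sum(covs) / n_win) / np.sqrt(
        (sum(vxs) / n_win) * (sum(vys) / n_win)
    )


def brute_weights(x, y, freqs, sr, degree, n):
    """Cross-periodogram magnitude at the nearest FFT bin, renormalized."""
    xd = brute_polyfit_residuals(x, degree)
    yd = brute_polyfit_residuals(y, degree)
    spec = np.fft.rfft(xd) * np.conj(np.fft.rfft(yd))
    bins = np.fft.rfftfreq(n, d=1.0 / sr)
    w = np.array([np.abs(spec[np.argmin(np.abs(bins - f))]) for f in freqs])
    return w / w.sum()


def brute_mdc3(x, y, f_min, f_max, f_step, sr, degree):
    """Straight-line transcription of the MDC3 pseudocode."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    n_freq = int(np.floor((f_max - f_min) / f_step + 1e-9)) + 1
    freqs = [f_min + k * f_step for k in range(n_freq)]
    scales = [int(round(sr / f)) for f in freqs]
    kept = [(f, s) for f, s in zip(freqs, scales) if degree + 2 <= s <= n]
    weights = brute_weights(x, y, [f for f, _ in kept], sr, degree, n)
    z = 0.0
    for (f, s), w in zip(kept, weights):
        c = brute_dccc(x, y, s, degree)
        c = min(max(c, -1 + 1e-12), 1 - 1e-12)
        z += w * np.arctanh(c)
    return np.tanh(z)


def brute_lagged_cov(xhat, yhat, direction, min_overlap=2):
    """Exhaustive scan over lags; ties to smaller |lag|, then negative lag."""
    xhat = np.asarray(xhat, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    s = len(xhat)
    lag_range = range(-(s - 1), 0) if direction == "leading" else range(1, s)
    results = []
    for k in lag_range:
        prods = [
            xhat[t + k] * yhat[t]
            for t in range(s) if 0 <= t + k < s
        ]
        if len(prods) < min_overlap:
            continue
        results.append((k, sum(prods) / len(prods)))
    best = max(abs(c) for _, c in results)
    winners = [(k, c) for k, c in results if abs(c) == best]
    winners.sort(key=lambda kc: (abs(kc[0]), kc[0]))
    return winners[0][1]


def brute_dmdc3(x, y, f_min, f_max, f_step, sr, degree):
    """Directed pipeline with the lagged-covariance numerator, by loops."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    n_freq = int(np.floor((f_max - f_min) / f_step + 1e-9)) + 1
    freqs = [f_min + k * f_step for k in range(n_freq)]
    scales = [int(round(sr / f)) for f in freqs]
    kept = [(f, s) for f, s in zip(freqs, scales) if degree + 2 <= s <= n]
    weights = brute_weights(x, y, [f for f, _ in kept], sr, degree, n)
    out = {}
    for direction in ("leading", "lagging"):
        z = 0.0
        for (f, s), w in zip(kept, weights):
            n_win = n // s
            nums, vxs, vys = [], [], []
            for i in range(n_win):
                xw = brute_polyfit_residuals(x[i * s:(i + 1) * s], degree)
                yw = brute_polyfit_residuals(y[i * s:(i + 1) * s], degree)
                nums.append(brute_lagged_cov(xw, yw, direction))
                vxs.append(np.mean(xw ** 2))
                vys.append(np.mean(yw ** 2))
            ratio = np.mean(nums) / np.sqrt(np.mean(vxs) * np.mean(vys))
            ratio = min(max(ratio, -1 + 1e-12), 1 - 1e-12)
            z += w * np.arctanh(ratio)
        out[direction] = np.tanh(z)
    return out["leading"], out["lagging"]


def brute_bh(pvalues):
    """Direct Benjamini-Hochberg step-up with monotone enforcement."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted
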