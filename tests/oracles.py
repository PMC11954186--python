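"""Independent oracles used by the unit and acceptance suites.

Deliberately brute force and kept free of the library code paths they
check: the grid search never touches the OLS/closed-form transforms, the
IQR filter is a literal loop over the rule, and the bootstrap refits with a
bare lstsq.
"""

import numpy as np


def grid_search_sinusoid(y, months, n_grid=61, refinements=2):
    """Best (amplitude, acrophase) by direct RSS minimisation on a grid.

    Model: y = b0 + A*cos(2*pi*(month-1)/12 - phi); for fixed (A, phi) the
    optimal b0 is the residual mean. The grid is refined ``refinements``
    times around the incumbent.
    """
    y = np.asarray(y, float)
    theta = 2.0 * np.pi * (np.asarray(months, float) - 1) / 12.0
    amp_lo, amp_hi = 0.0, 3.0 * y.std()
    phi_lo, phi_hi = -np.pi, np.pi
    best = (np.inf, 0.0, 0.0)
    for _ in range(refinements + 1):
        amps = np.linspace(amp_lo, amp_hi, n_grid)
        phis = np.linspace(phi_lo, phi_hi, n_grid)
        for a in amps:
            fitted = a * np.cos(theta[None, :] - phis[:, None])
            resid = y[None, :] - fitted
            resid -= resid.mean(axis=1, keepdims=True)
            rss = (resid**2).sum(axis=1)
            j = int(np.argmin(rss))
            if rss[j] < best[0]:
                best = (rss[j], a, phis[j])
        amp_step = (amp_hi - amp_lo) / (n_grid - 1)
        phi_step = (phi_hi - phi_lo) / (n_grid - 1)
        amp_lo = max(0.0, best[1] - 2 * amp_step)
        amp_hi = best[1] + 2 * amp_step
        phi_lo, phi_hi = best[2] - 2 * phi_step, best[2] + 2 * phi_step
    return best[1], best[2]


def brute_force_iqr_filter(values, k=4.0):
    """Literal per-value application of the |v - median| <= k*IQR rule."""
    v = [float(x) for x in values]
    finite = [x for x in v if np.isfinite(x)]
    srt = sorted(finite)
    med = float(np.median(srt))
    q1 = float(np.quantile(srt, 0.25))
    q3 = float(np.quantile(srt, 0.75))
    iqr = q3 - q1
    keep = []
    for x in v:
        if not np.isfinite(x):
            keep.append(False)
        elif iqr == 0.0:
            keep.append(x == med)
        else:
            keep.append(abs(x - med) <= k * iqr)
    return np.array(keep)


def bootstrap_seasonal_se(y, months, n_boot=1000, seed=0):
    """Nonparametric bootstrap SEs of amplitude and acrophase.

    Each resample is refit with a bare least-squares on the sine/cosine
    design; angles are summarised on the circle.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    months = np.asarray(months)
    n = len(y)
    theta = 2.0 * np.pi * (months - 1) / 12.0
    X = np.column_stack([np.ones(n), np.cos(theta), np.sin(theta)])
    amps = np.empty(n_boot)
    phis = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        beta = np.linalg.lstsq(X[idx], y[idx], rcond=None)[0]
        amps[b] = np.hypot(beta[1], beta[2])
        phis[b] = np.arctan2(beta[2], beta[1])
    # circular SD for the phase (effects here are far from the wrap point)
    mean_angle = np.angle(np.mean(np.exp(1j * phis)))
    dev = np.angle(np.exp(1j * (phis - mean_angle)))
    return amps.std(ddof=1), dev.std(ddof=1)
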