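"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package
implementation it checks: direct per-split SSE scans for 1-D 2-means, an
explicitly written-out Cox partial likelihood maximized on a grid, a
Beta-likelihood grid/Nelder-Mead search for the two-part Dirichlet
regression, and exhaustive permutation enumeration for Spearman.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, stats


def two_means_oracle(x: np.ndarray) -> tuple[float, float, float]:
    """Best 2-cluster split of scalars by direct SSE scan over breakpoints."""
    xs = np.sort(np.asarray(x, dtype=float))
    best = (np.inf, None)
    for split in range(1, xs.size):
        left, right = xs[:split], xs[split:]
        sse = left.var() * left.size + right.var() * right.size
        if sse < best[0] - 1e-15:
            best = (sse, split)
    split = best[1]
    low, high = xs[:split].mean(), xs[split:].mean()
    return low, high, 0.5 * (low + high)


def cox_partial_loglik(beta: np.ndarray, times, events, x) -> np.ndarray:
    """Breslow log partial likelihood, written out directly (grid-friendly).

    ``beta`` may be a vector of candidate values for a single covariate.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = np.zeros_like(beta)
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(
            np.sum(np.exp(beta[:, None] * x[None, risk]), axis=1)
        )
    return ll


def cox_grid_oracle(times, events, x, lo=-5.0, hi=5.0, step=1e-4) -> float:
    grid = np.arange(lo, hi + step, step)
    ll = cox_partial_loglik(grid, times, events, x)
    return float(grid[np.argmax(ll)])


def _beta_loglik(theta, x, y1):
    a = np.exp(theta[0] + theta[1] * x)
    b = np.exp(theta[2] + theta[3] * x)
    return float(np.sum(stats.beta.logpdf(y1, a, b)))


def beta_regression_grid_oracle(y1, x, slope_lo=-3.0, slope_hi=3.0) -> float:
    """Mean-slope MLE of the two-part model via scipy.stats.beta + grid search.

    Grids the mean-model contrast s = slope_habitat - slope_rest, profiling
    the remaining three parameters (two intercepts and the common slope part)
    with derivative-free Nelder-Mead; refines the grid down to 1e-4.
    """
    y1 = np.asarray(y1, float)
    x = np.asarray(x, float)

    def profile(slope, start):
        def nll(rest):
            # rest = (c0, d0, u): alpha = exp(c0 + u x), beta = exp(d0 + (u - slope) x)
            return -_beta_loglik([rest[0], rest[2], rest[1], rest[2] - slope], x, y1)

        res = optimize.minimize(nll, start, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        return -res.fun, res.x

    start = np.zeros(3)
    lo, hi, step = slope_lo, slope_hi, 0.05
    best_slope = 0.0
    for step in (0.05, 1e-3, 1e-4):
        grid = np.arange(lo, hi + step / 2, step)
        lls = []
        for s in grid:
            ll, start = profile(s, start)
            lls.append(ll)
        best_slope = float(grid[int(np.argmax(lls))])
        lo, hi = best_slope - 2 * step, best_slope + 2 * step
    return best_slope


def spearman_exact(x, y) -> tuple[float, float]:
    """Midrank Spearman rho and exact two-sided permutation p (n <= 7)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = x.size
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= abs(rho) - 1e-12
        total += 1
    return float(rho), count / total
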