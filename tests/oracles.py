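"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from the defining formulas —
explicit loops and closed-form sums — independently of the package code
paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def trapezoid_brute(times, concs) -> float:
    """Sum of per-interval trapezoid areas, one pair at a time."""
    total = 0.0
    for i in range(len(times) - 1):
        total += (times[i + 1] - times[i]) * (concs[i] + concs[i + 1]) / 2.0
    return total


def weighted_line_fit(x, y, w) -> tuple[float, float]:
    """Closed-form weighted normal equations for y = a*x + b."""
    sw = sum(w)
    sx = sum(wi * xi for wi, xi in zip(w, x))
    sy = sum(wi * yi for wi, yi in zip(w, y))
    sxx = sum(wi * xi * xi for wi, xi in zip(w, x))
    sxy = sum(wi * xi * yi for wi, xi, yi in zip(w, x, y))
    a = (sw * sxy - sx * sy) / (sw * sxx - sx * sx)
    b = (sy - a * sx) / sw
    return a, b


def sample_sd(values) -> float:
    """n-1 denominator standard deviation from the definition."""
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def cd_elastic_net(X, y, alpha, l1_ratio, n_iter=200_000, tol=1e-14):
    """Cyclic coordinate descent on the elastic-net objective

    (1/(2n))||y - b0 - X beta||^2 + alpha*l1*||beta||_1
    + (alpha*(1-l1)/2)*||beta||_2^2,

    with the intercept updated by the residual mean each sweep.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    b0 = y.mean()
    col_sq = (X**2).mean(axis=0)
    for _ in range(n_iter):
        max_delta = 0.0
        r = y - b0 - X @ beta
        b0_new = b0 + r.mean()
        max_delta = max(max_delta, abs(b0_new - b0))
        b0 = b0_new
        for j in range(p):
            r = y - b0 - X @ beta
            rho = (X[:, j] * (r + X[:, j] * beta[j])).mean()
            z = abs(rho) - alpha * l1_ratio
            new = math.copysign(max(z, 0.0), rho) / (col_sq[j] + alpha * (1 - l1_ratio))
            max_delta = max(max_delta, abs(new - beta[j]))
            beta[j] = new
        if max_delta < tol:
            break
    return b0, beta


def quantile_linear(values, q) -> float:
    """Linear-interpolation quantile from the definition."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def pqn_quotient(sample, reference) -> float:
    """Median over positive-reference features of sample/reference."""
    quotients = [s / r for s, r in zip(sample, reference) if r > 0]
    quotients.sort()
    n = len(quotients)
    mid = n // 2
    return quotients[mid] if n % 2 else (quotients[mid - 1] + quotients[mid]) / 2.0


def histogram_brute(values, edges):
    """Per-bin counts; the last bin is closed on the right (numpy rule)."""
    counts = [0] * (len(edges) - 1)
    for v in values:
        for b in range(len(counts)):
            last = b == len(counts) - 1
            if edges[b] <= v < edges[b + 1] or (last and v == edges[b + 1]):
                counts[b] += 1
                break
    return counts


def explained_variance_formula(y, yhat) -> float:
    n = len(y)
    res = [yi - pi for yi, pi in zip(y, yhat)]
    mr = sum(res) / n
    my = sum(y) / n
    var_r = sum((r - mr) ** 2 for r in res) / n
    var_y = sum((yi - my) ** 2 for yi in y) / n
    return 1.0 - var_r / var_y


def mape_formula(y, yhat) -> float:
    return 100.0 * sum(abs(yi - pi) / abs(yi) for yi, pi in zip(y, yhat)) / len(y)


def rmse_formula(y, yhat) -> float:
    return math.sqrt(sum((yi - pi) ** 2 for yi, pi in zip(y, yhat)) / len(y))
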