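"""Naive reference implementations used as independent oracles.

Everything here is deliberately written the slow, explicit way (python loops,
normal-equations line fits) and shares no code with the package internals.
"""

import numpy as np


def ols_line_fit(k, v):
    """Straight-line fit v ~ a + b*k by explicit normal equations."""
    k = np.asarray(k, dtype=float)
    v = np.asarray(v, dtype=float)
    n = k.size
    sk, sv = k.sum(), v.sum()
    skk, skv = (k * k).sum(), (k * v).sum()
    denom = n * skk - sk * sk
    b = (n * skv - sk * sv) / denom
    a = (sv - b * sk) / n
    return a + b * k


def naive_window_cov(M, N, S, i):
    """Detrended covariance of window i (1-based), explicit loop."""
    k = np.arange(i, i + S + 1)
    Mw = np.array([M[kk - 1] for kk in k], dtype=float)
    Nw = np.array([N[kk - 1] for kk in k], dtype=float)
    Mfit = ols_line_fit(k, Mw)
    Nfit = ols_line_fit(k, Nw)
    total = 0.0
    for j in range(S + 1):
        total += (Mw[j] - Mfit[j]) * (Nw[j] - Nfit[j])
    return total / (S + 1)


def naive_variance_profile(M, N, S):
    L = len(M)
    total = 0.0
    for i in range(1, L - S + 1):
        total += naive_window_cov(M, N, S, i)
    return total / (L - S)


def naive_dcca_coefficient(colA, colB, S):
    M = [float(sum(colA[: k + 1])) for k in range(len(colA))]
    N = [float(sum(colB[: k + 1])) for k in range(len(colB))]
    fxy = naive_variance_profile(M, N, S)
    fxx = naive_variance_profile(M, M, S)
    fyy = naive_variance_profile(N, N, S)
    return fxy / (np.sqrt(fxx) * np.sqrt(fyy))


def naive_scatter_matrices(X, y, A):
    """O(n^2) double-loop local scatter matrices."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    counts = {c: int(np.sum(y == c)) for c in np.unique(y)}
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for i in range(n):
        for j in range(n):
            diff = (X[i] - X[j])[:, None]
            outer = diff @ diff.T
            if y[i] == y[j]:
                ww = A[i, j] / counts[y[i]]
                wb = A[i, j] * (1.0 / n - 1.0 / counts[y[i]])
            else:
                ww = 0.0
                wb = 1.0 / n
            Sw += 0.5 * ww * outer
            Sb += 0.5 * wb * outer
    return Sw, Sb


def classical_within_scatter(X, y):
    """Sum over classes of sum of (x - class mean) outer products."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    S = np.zeros((d, d))
    for c in np.unique(y):
        block = X[y == c]
        mu = block.mean(axis=0)
        for row in block:
            diff = (row - mu)[:, None]
            S += diff @ diff.T
    return S


def naive_column_means(values):
    L, width = values.shape
    out = []
    for j in range(width):
        total = 0.0
        for i in range(L):
            total += values[i, j]
        out.append(total / L)
    return np.array(out)


def naive_lag_theta(values, g):
    L, width = values.shape
    out = []
    for j in range(width):
        total = 0.0
        for i in range(L - g):
            total += (values[i, j] - values[i + g, j]) ** 2
        out.append(total / (L - g))
    return np.array(out)
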