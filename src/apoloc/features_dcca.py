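"""Detrended cross-correlation coefficients between profile columns.

Each of the 20 normalized profile columns is integrated into a running sum,
the integrated series are split into all L-S overlapping windows of S+1
points (step 1), each window is detrended by its own ordinary-least-squares
line against the position index, and the coefficient of a column pair is the
ratio of the mean residual cross-product to the geometric mean of the two
mean residual squares.  All C(20,2) = 190 unordered pairs, taken
lexicographically over the fixed column order, make up the feature vector.

The optimized path exploits the fact that the OLS hat matrix depends only on
the window length: residuals for every window of a series are one matrix
product, and all 190 pair coefficients come from a single 20 x 20 Gram
matrix of flattened residuals.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import PSSM_COLUMNS, NormPSSM

logger = logging.getLogger(__name__)

DEFAULT_S = 40

#: Unordered column-pair ordering: (0,1), (0,2), ..., (18,19).
PAIR_INDICES: tuple[tuple[int, int], ...] = tuple(combinations(range(20), 2))

#: Detrended variance below this fraction of the profile's mean square is
#: indistinguishable from rounding noise and treated as exactly zero.
_DEGENERATE_REL = 1e-24


def dcca_feature_names() -> list[str]:
    return [f"dcca_{PSSM_COLUMNS[a]}{PSSM_COLUMNS[b]}" for a, b in PAIR_INDICES]


def integrated_profile(col: np.ndarray) -> np.ndarray:
    """Running cumulative sum of one profile column."""
    col = np.asarray(col, dtype=float)
    if col.ndim != 1 or col.size < 1:
        raise ValueError("column must be a non-empty 1-D array")
    return np.cumsum(col)


def _check_window(L: int, S: int) -> None:
    if S < 1:
        raise ValueError(f"window parameter S must be >= 1, got {S}")
    if S >= L:
        raise ValueError(
            f"window exceeds profile: S={S} needs length >= {S + 1}, got L={L}"
        )


def _residual_projector(S: int) -> np.ndarray:
    """I - H for the OLS line fit on S+1 equally spaced points."""
    k = np.arange(S + 1, dtype=float)
    X = np.column_stack([np.ones(S + 1), k])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    return np.eye(S + 1) - H


def _window_residuals(profile: np.ndarray, S: int) -> np.ndarray:
    """(L-S) x (S+1) matrix of per-window OLS residuals of one series."""
    profile = np.asarray(profile, dtype=float)
    _check_window(profile.size, S)
    windows = sliding_window_view(profile, S + 1)  # (L-S, S+1)
    return windows @ _residual_projector(S).T


def window_detrended_cov(
    M: np.ndarray, N: np.ndarray, S: int, i: int
) -> float:
    """Detrended covariance of one window starting at 1-based position i.

    The window is the S+1 points k = i..i+S of the integrated series; each
    series gets its own least-squares line fit against k, and the value is
    the mean product of the two residual series.
    """
    M = np.asarray(M, dtype=float)
    N = np.asarray(N, dtype=float)
    if M.shape != N.shape:
        raise ValueError("integrated profiles must have equal length")
    L = M.size
    _check_window(L, S)
    if not 1 <= i <= L - S:
        raise IndexError(f"window start {i} out of range 1..{L - S}")
    P = _residual_projector(S)
    rm = P @ M[i - 1 : i + S]
    rn = P @ N[i - 1 : i + S]
    return float(rm @ rn) / (S + 1)


def dcca_variance_profile(M: np.ndarray, N: np.ndarray, S: int) -> float:
    """Mean of the per-window detrended covariances over all L-S windows."""
    M = np.asarray(M, dtype=float)
    N = np.asarray(N, dtype=float)
    if M.shape != N.shape:
        raise ValueError("integrated profiles must have equal length")
    rm = _window_residuals(M, S)
    rn = _window_residuals(N, S)
    return float((rm * rn).mean())


def dcca_coefficient(colA: np.ndarray, colB: np.ndarray, S: int) -> float:
    """Detrended cross-correlation coefficient of two columns; in [-1, 1].

    A zero denominator (a series exactly linear inside every window) yields
    0 with a warning.
    """
    colA = np.asarray(colA, dtype=float)
    colB = np.asarray(colB, dtype=float)
    if colA.shape != colB.shape:
        raise ValueError(
            f"column length mismatch: {colA.shape} vs {colB.shape}"
        )
    M = integrated_profile(colA)
    N = integrated_profile(colB)
    fxy = dcca_variance_profile(M, N, S)
    fxx = dcca_variance_profile(M, M, S)
    fyy = dcca_variance_profile(N, N, S)
    # variances at rounding-noise level (exactly linear profiles) count as 0
    if fxx <= _DEGENERATE_REL * np.mean(M * M) or \
            fyy <= _DEGENERATE_REL * np.mean(N * N):
        logger.warning("degenerate detrended variance; coefficient set to 0")
        return 0.0
    denom = np.sqrt(fxx) * np.sqrt(fyy)
    # Cauchy-Schwarz bounds |rho| by 1 up to float rounding; clip the excess.
    return float(np.clip(fxy / denom, -1.0, 1.0))


def dcca_features(p: NormPSSM, S: int = DEFAULT_S) -> np.ndarray:
    """All 190 pair coefficients of a normalized profile, declared ordering."""
    if S >= p.L:
        raise ValueError(
            f"protein {p.protein_id!r} of length {p.L} is too short for "
            f"window parameter S={S} (needs length >= {S + 1})"
        )
    integrated = np.cumsum(p.values, axis=0)  # L x 20
    proj = _residual_projector(S)
    windows = sliding_window_view(integrated, S + 1, axis=0)  # (L-S, 20, S+1)
    residuals = windows @ proj.T  # (L-S, 20, S+1)
    flat = residuals.transpose(1, 0, 2).reshape(20, -1)  # 20 x (L-S)(S+1)
    gram = flat @ flat.T
    diag = np.diag(gram)
    # same rounding-noise floor as the scalar route, per column
    floors = _DEGENERATE_REL * flat.shape[1] * (integrated ** 2).mean(axis=0)
    degenerate = diag <= floors
    out = np.empty(len(PAIR_INDICES))
    for idx, (a, b) in enumerate(PAIR_INDICES):
        denom = np.sqrt(diag[a]) * np.sqrt(diag[b])
        if degenerate[a] or degenerate[b]:
            logger.warning(
                "protein %s: degenerate detrended variance for pair (%d, %d); "
                "coefficient set to 0", p.protein_id, a + 1, b + 1,
            )
            out[idx] = 0.0
        else:
            out[idx] = np.clip(gram[a, b] / denom, -1.0, 1.0)
    return out


def max_window(L: int) -> int:
    """Largest admissible S for a profile of length L (at least one window)."""
    if L < 2:
        raise ValueError(f"profile of length {L} admits no window")
    return L - 1
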