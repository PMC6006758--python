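"""Local Fisher discriminant analysis.

Supervised linear reduction maximizing the trace ratio of a locality-weighted
between-class scatter to the corresponding within-class scatter.  Affinities
use per-sample local scaling (distance to the K-th nearest neighbor); the
transform comes from the top generalized eigenvectors of S_b t = lambda S_w t,
solved against a lightly ridged S_w so that small leave-one-out training sets
stay well posed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist, pdist, squareform

logger = logging.getLogger(__name__)

DEFAULT_K = 7
DEFAULT_R = 10

#: Floor applied to a local scale that collapses to 0 on duplicate points.
SIGMA_FLOOR = 1e-12


@dataclass
class AffinityMatrix:
    """Symmetric pairwise affinities with the local scales that built them."""

    A: np.ndarray
    sigma: np.ndarray


@dataclass
class LfdaModel:
    """Fitted d x r transform with the scatter matrices behind it."""

    T: np.ndarray
    eigenvalues: np.ndarray
    Sw: np.ndarray
    Sb: np.ndarray
    r: int
    K: int
    epsilon: float
    affinity: str = "plain"

    @property
    def d(self) -> int:
        return self.T.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "T": self.T.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "r": self.r,
            "K": self.K,
            "epsilon": self.epsilon,
            "affinity": self.affinity,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LfdaModel":
        payload = json.loads(Path(path).read_text())
        T = np.array(payload["T"], dtype=float)
        d = T.shape[0]
        return cls(
            T=T,
            eigenvalues=np.array(payload["eigenvalues"], dtype=float),
            Sw=np.full((d, d), np.nan),
            Sb=np.full((d, d), np.nan),
            r=int(payload["r"]),
            K=int(payload["K"]),
            epsilon=float(payload["epsilon"]),
            affinity=payload["affinity"],
        )


def local_scaling(X: np.ndarray, K: int = DEFAULT_K) -> np.ndarray:
    """Distance from each sample to its K-th nearest neighbor (self excluded).

    Scales that collapse to 0 on duplicated points are floored at
    ``SIGMA_FLOOR`` with a warning.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= K:
        raise ValueError(
            f"local scaling needs more than K={K} samples, got n={n}; "
            f"lower K or add samples"
        )
    D = squareform(pdist(X))
    # K-th neighbor excluding self = (K+1)-th smallest including the 0 diagonal.
    sigma = np.partition(D, K, axis=1)[:, K]
    if np.any(sigma <= 0):
        logger.warning(
            "%d local scales were 0 (duplicate points); floored at %g",
            int(np.sum(sigma <= 0)), SIGMA_FLOOR,
        )
        sigma = np.maximum(sigma, SIGMA_FLOOR)
    return sigma


def affinity_matrix(
    X: np.ndarray, sigma: np.ndarray, variant: str = "plain"
) -> AffinityMatrix:
    """exp(-dist / (sigma_i sigma_j)) pairwise affinities, unit diagonal.

    ``variant='squared'`` uses the squared distance in the exponent instead
    (the classical local-scaling construction).
    """
    X = np.asarray(X, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("all local scales must be positive")
    D = squareform(pdist(X))
    if variant == "squared":
        D = D ** 2
    elif variant != "plain":
        raise ValueError(f"unknown affinity variant {variant!r}")
    A = np.exp(-D / np.outer(sigma, sigma))
    np.fill_diagonal(A, 1.0)
    return AffinityMatrix(A=A, sigma=sigma)


def _pair_weights(
    y: np.ndarray, A: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-class pair weight matrices from the affinities."""
    n = y.size
    same = y[:, None] == y[None, :]
    counts = {c: int(np.sum(y == c)) for c in np.unique(y)}
    n_l = np.array([counts[c] for c in y], dtype=float)  # class size per sample
    Ww = np.where(same, A / n_l[:, None], 0.0)
    Wb = np.where(same, A * (1.0 / n - 1.0 / n_l[:, None]), 1.0 / n)
    return Ww, Wb


def _scatter_from_weights(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    # (1/2) sum_ij W_ij (x_i - x_j)(x_i - x_j)^T  ==  X^T (D - W) X
    Wsym = 0.5 * (W + W.T)
    Lmat = np.diag(Wsym.sum(axis=1)) - Wsym
    S = X.T @ Lmat @ X
    return 0.5 * (S + S.T)


def local_scatter_matrices(
    X: np.ndarray,
    y: np.ndarray,
    A: np.ndarray | AffinityMatrix,
    classes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Locality-weighted within-class and between-class scatter matrices."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if isinstance(A, AffinityMatrix):
        A = A.A
    A = np.asarray(A, dtype=float)
    n = X.shape[0]
    if y.size != n or A.shape != (n, n):
        raise ValueError("X, y and A have inconsistent shapes")
    if classes is not None:
        present = set(np.unique(y).tolist())
        missing = [c for c in classes if c not in present]
        if missing:
            raise ValueError(f"classes with 0 members: {missing}")
    Ww, Wb = _pair_weights(y, A)
    return _scatter_from_weights(X, Ww), _scatter_from_weights(X, Wb)


def lfda_fit(
    X: np.ndarray,
    y: np.ndarray,
    r: int = DEFAULT_R,
    K: int = DEFAULT_K,
    affinity: str = "plain",
    epsilon_scale: float = 1e-6,
) -> LfdaModel:
    """Fit the reduction: top-r generalized eigenvectors of S_b t = lambda S_w t.

    S_w is regularized to S_w + eps*I with eps = epsilon_scale * trace(S_w)/d.
    Returned columns have unit Euclidean norm with the largest-magnitude entry
    positive, ordered by descending eigenvalue.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    c = np.unique(y).size
    if c < 2:
        raise ValueError("need at least two classes")
    if n <= c:
        raise ValueError(f"need more samples than classes (n={n}, c={c})")
    if r < 1:
        raise ValueError(f"target dimension must be >= 1, got {r}")
    if r > d:
        raise ValueError(
            f"target dimension r={r} exceeds the {d} available eigenpairs; "
            f"choose r <= {d}"
        )

    sigma = local_scaling(X, K=K)
    aff = affinity_matrix(X, sigma, variant=affinity)
    Sw, Sb = local_scatter_matrices(X, y, aff)

    eps = epsilon_scale * np.trace(Sw) / d
    if eps <= 0:
        eps = 1e-12
    Swr = Sw + eps * np.eye(d)

    eigvals, eigvecs = scipy.linalg.eigh(Sb, Swr)
    order = np.argsort(eigvals)[::-1][:r]
    vals = eigvals[order]
    T = eigvecs[:, order]
    T = T / np.linalg.norm(T, axis=0, keepdims=True)
    # Deterministic sign: largest-magnitude entry of each column positive.
    flip = T[np.abs(T).argmax(axis=0), np.arange(r)] < 0
    T[:, flip] *= -1.0
    return LfdaModel(T=T, eigenvalues=vals, Sw=Sw, Sb=Sb, r=r, K=K,
                     epsilon=float(eps), affinity=affinity)


def lfda_transform(model: LfdaModel, Xnew: np.ndarray) -> np.ndarray:
    """Project rows-as-samples data into the fitted r-dimensional space."""
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.d:
        raise ValueError(
            f"expected {model.d} feature columns, got {Xnew.shape[1]}"
        )
    return Xnew @ model.T
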