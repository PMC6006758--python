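"""Pseudo-profile features: per-column means plus lagged squared-difference terms.

For a normalized L x 20 profile P the descriptor is the concatenation of the
20 column means with, for each lag g = 1..xi, the 20 values

    theta_j^g = (1/(L-g)) * sum_{i=1}^{L-g} (P[i,j] - P[i+g,j])**2

giving a vector of length 20 + 20*xi.  xi = 0 yields the means alone.
"""

from __future__ import annotations

import numpy as np

from .io_formats import PSSM_COLUMNS, NormPSSM

DEFAULT_XI = 3


def column_means(p: NormPSSM) -> np.ndarray:
    """Mean of each profile column; 20 values in column order."""
    return p.values.mean(axis=0)


def lag_theta(p: NormPSSM, g: int) -> np.ndarray:
    """Mean squared difference between rows g apart, per column.

    Raises if the lag reaches the profile length (no valid row pairs).
    """
    if g < 1:
        raise ValueError(f"lag must be >= 1, got {g}")
    if g >= p.L:
        raise ValueError(
            f"lag {g} exceeds sequence length {p.L} for protein "
            f"{p.protein_id!r}"
        )
    diff = p.values[:-g] - p.values[g:]
    return (diff * diff).mean(axis=0)


def psepssm_features(p: NormPSSM, xi: int = DEFAULT_XI) -> np.ndarray:
    """Concatenated [means | theta^1 | ... | theta^xi]; length 20 + 20*xi."""
    if xi < 0:
        raise ValueError(f"xi must be >= 0, got {xi}")
    blocks = [column_means(p)]
    for g in range(1, xi + 1):
        blocks.append(lag_theta(p, g))
    return np.concatenate(blocks)


def psepssm_feature_names(xi: int = DEFAULT_XI) -> list[str]:
    names = [f"P_mean_{aa}" for aa in PSSM_COLUMNS]
    for g in range(1, xi + 1):
        names.extend(f"theta_g{g}_{aa}" for aa in PSSM_COLUMNS)
    return names
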