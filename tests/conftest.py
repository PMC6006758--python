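import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from apoloc.io_formats import NormPSSM, RawPSSM


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_norm_pssm(rng, L=30, protein_id="P1"):
    """Random normalized profile with values safely inside (0, 1)."""
    return NormPSSM(protein_id, rng.uniform(0.05, 0.95, size=(L, 20)))


def make_raw_pssm(rng, L=30, protein_id="P1"):
    scores = rng.integers(-9, 12, size=(L, 20))
    from apoloc.io_formats import PSSM_COLUMNS

    residues = "".join(PSSM_COLUMNS[j] for j in scores.argmax(axis=1))
    return RawPSSM(protein_id=protein_id, scores=scores, residues=residues)


@pytest.fixture
def norm_pssm(rng):
    return make_norm_pssm(rng)


@pytest.fixture
def raw_pssm(rng):
    return make_raw_pssm(rng)
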