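"""Synthetic labeled profile datasets with tunable class structure.

Each class draws profiles from a Gaussian field whose three knobs map onto
the three feature families downstream:

* ``separation`` shifts the per-class column-mean profile (column means),
* ``lag_signal`` sets class-dependent row-to-row AR(1) autocorrelation
  (lagged squared-difference terms),
* ``pair_signal`` mixes columns through a class-specific loading matrix
  (inter-column detrended cross-correlations).

Scores are rounded to integers and clipped to the typical [-9, 11] log-odds
range; sequences take each row's argmax residue, so profile and sequence are
mutually consistent.  Everything is reproducible from the seed alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    PSSM_COLUMNS,
    SCORE_RANGE,
    ProteinRecord,
    RawPSSM,
    write_labels,
)

logger = logging.getLogger(__name__)

_NOISE_SD = 3.0


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset draw.

    ``n_per_class`` may be one count shared by all classes or a per-class
    tuple (real benchmark sets are imbalanced, e.g. 43/30/13/12).
    """

    n_classes: int = 3
    n_per_class: int | tuple[int, ...] = 30
    length_range: tuple[int, int] = (50, 120)
    separation: float = 6.0
    lag_signal: float = 0.0
    pair_signal: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("counts must be >= 1")
        counts = self.class_counts()
        if len(counts) != self.n_classes or any(c < 1 for c in counts):
            raise ValueError(
                f"n_per_class must give {self.n_classes} counts >= 1, "
                f"got {self.n_per_class!r}"
            )
        lmin, lmax = self.length_range
        if lmin < 2 or lmax < lmin:
            raise ValueError(f"bad length range {self.length_range}")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0 <= self.lag_signal < 1:
            raise ValueError("lag_signal must be in [0, 1)")
        if not -1 <= self.pair_signal <= 1:
            raise ValueError("pair_signal must be in [-1, 1]")

    def class_counts(self) -> tuple[int, ...]:
        if isinstance(self.n_per_class, int):
            return (self.n_per_class,) * self.n_classes
        return tuple(int(c) for c in self.n_per_class)


def _class_loadings(rng: np.random.Generator, pair_signal: float) -> np.ndarray:
    """Column-mixing matrix B with cov = B B^T and unit diagonal."""
    B = np.eye(20) + pair_signal * rng.normal(0.0, 0.3, size=(20, 20))
    norms = np.linalg.norm(B, axis=1, keepdims=True)
    return B / norms


def generate_dataset(
    spec: SynthSpec, downstream_S: int | None = None
) -> tuple[list[ProteinRecord], list[RawPSSM], dict[str, int]]:
    """Draw a labeled set of (sequence, profile) pairs per the spec."""
    if downstream_S is not None and spec.length_range[0] <= downstream_S:
        logger.warning(
            "minimum length %d is <= downstream window parameter S=%d; "
            "some proteins may be rejected downstream",
            spec.length_range[0], downstream_S,
        )
    rng = np.random.default_rng(spec.seed)
    lmin, lmax = spec.length_range
    lo, hi = SCORE_RANGE

    base_mean = rng.normal(0.0, 1.0, size=20)
    records: list[ProteinRecord] = []
    pssms: list[RawPSSM] = []
    labels: dict[str, int] = {}
    for cls, count in enumerate(spec.class_counts()):
        direction = rng.normal(0.0, 1.0, size=20)
        direction /= np.linalg.norm(direction)
        mu = base_mean + spec.separation * direction
        B = _class_loadings(rng, spec.pair_signal)
        # class-dependent autocorrelation in [0, lag_signal]
        rho = spec.lag_signal * (cls + 1) / spec.n_classes
        for k in range(count):
            L = int(rng.integers(lmin, lmax + 1))
            innov = rng.normal(0.0, 1.0, size=(L, 20)) @ B.T
            field = np.empty((L, 20))
            field[0] = innov[0]
            scale = np.sqrt(1.0 - rho ** 2)
            for t in range(1, L):
                field[t] = rho * field[t - 1] + scale * innov[t]
            scores = np.clip(np.rint(mu + _NOISE_SD * field), lo, hi).astype(int)
            seq = "".join(PSSM_COLUMNS[j] for j in scores.argmax(axis=1))
            pid = f"SYN{cls}_{k:03d}"
            records.append(ProteinRecord(id=pid, sequence=seq, label=cls))
            pssms.append(RawPSSM(protein_id=pid, scores=scores, residues=seq))
            labels[pid] = cls
    return records, pssms, labels


def write_pssm_fixture(p: RawPSSM, path: str | Path) -> None:
    """Write a profile in the 40-column NCBI ASCII dialect (zero percentages)."""
    path = Path(path)
    residues = p.residues if p.residues is not None else "A" * p.L
    header_letters = "  ".join(PSSM_COLUMNS)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"            {header_letters}   {header_letters}",
    ]
    for i in range(p.L):
        score_part = " ".join(f"{v:3d}" for v in p.scores[i])
        pct_part = " ".join("  0" for _ in range(20))
        lines.append(f"{i + 1:5d} {residues[i]}  {score_part}  {pct_part}")
    lines.append("")
    path.write_text("\n".join(lines) + "\n")


def write_dataset(
    out_dir: str | Path,
    records: list[ProteinRecord],
    pssms: list[RawPSSM],
    labels: dict[str, int],
) -> dict[str, Path]:
    """Emit FASTA + label TSV + one profile file per protein under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(exist_ok=True)

    fasta_path = out_dir / "proteins.fasta"
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for start in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[start : start + 60] + "\n")

    labels_path = out_dir / "labels.tsv"
    write_labels(labels, labels_path)

    for p in pssms:
        write_pssm_fixture(p, pssm_dir / f"{p.protein_id}.pssm")
    return {"fasta": fasta_path, "labels": labels_path, "pssm_dir": pssm_dir}
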