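"""Readers and writers for FASTA files, label tables, and PSI-BLAST ASCII profiles.

The profile parser accepts both the full NCBI ``-out_ascii_pssm`` layout
(position, residue, 20 integer log-odds columns, 20 percentage columns and
optional trailing statistics) and a bare 20-column layout carrying only the
score block.  Dialect is auto-detected per row from the field count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.special import expit

logger = logging.getLogger(__name__)

#: Fixed PSI-BLAST residue column order.
PSSM_COLUMNS: str = "ARNDCQEGHILKMFPSTWYV"

STANDARD_RESIDUES = frozenset(PSSM_COLUMNS)

#: Typical log-odds score range; values outside trigger a warning, not rejection.
SCORE_RANGE = (-9, 11)

#: Deterministic substitutions for ambiguous residue codes.
AMBIGUOUS_SUBSTITUTIONS: Mapping[str, str] = {"B": "N", "Z": "Q", "U": "C", "O": "K"}


@dataclass
class ProteinRecord:
    """A protein sequence with an optional integer class label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class RawPSSM:
    """L x 20 integer log-odds profile in PSI-BLAST column order."""

    protein_id: str
    scores: np.ndarray
    residues: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"profile for {self.protein_id!r} must be L x 20, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"profile for {self.protein_id!r} has no rows")
        lo, hi = SCORE_RANGE
        if self.scores.min() < lo or self.scores.max() > hi:
            logger.warning(
                "profile %s: scores outside typical range [%d, %d] "
                "(min=%d, max=%d); accepted",
                self.protein_id, lo, hi, self.scores.min(), self.scores.max(),
            )

    @property
    def L(self) -> int:
        return self.scores.shape[0]


@dataclass
class NormPSSM:
    """Sigmoid-normalized profile; every entry strictly inside (0, 1)."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(
                f"normalized profile for {self.protein_id!r} must be L x 20"
            )

    @property
    def L(self) -> int:
        return self.values.shape[0]


def sanitize_sequence(
    record_id: str, sequence: str, pssm: RawPSSM | None = None
) -> str:
    """Map non-standard residue codes onto the 20-letter alphabet.

    B/Z/U/O map to their canonical stand-ins; X and ``*`` take the residue
    with the highest raw profile score at that position when a profile is
    available, otherwise 'A'.  Every substitution is logged.
    """
    out = []
    for pos0, aa in enumerate(sequence.upper()):
        if aa in STANDARD_RESIDUES:
            out.append(aa)
            continue
        if aa in AMBIGUOUS_SUBSTITUTIONS:
            repl = AMBIGUOUS_SUBSTITUTIONS[aa]
        elif aa in ("X", "*"):
            if pssm is not None and pos0 < pssm.L:
                repl = PSSM_COLUMNS[int(np.argmax(pssm.scores[pos0]))]
            else:
                repl = "A"
        else:
            raise ValueError(
                f"protein {record_id!r}: unrecognized residue {aa!r} "
                f"at position {pos0 + 1}"
            )
        logger.warning(
            "protein %s: residue %r at position %d mapped to %r",
            record_id, aa, pos0 + 1, repl,
        )
        out.append(repl)
    return "".join(out)


def read_fasta(
    path: str | Path,
    labels: Mapping[str, int] | None = None,
    pssm_lookup: Mapping[str, RawPSSM] | None = None,
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Parameters
    ----------
    path:
        FASTA file; multi-line sequences allowed.
    labels:
        Optional id -> class-index mapping attached to each record.
    pssm_lookup:
        Optional id -> :class:`RawPSSM` mapping used to resolve X/``*``
        residues by the position's best-scoring column.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA header at line {lineno}: "
                        f"expected '>', got {line.strip()[:30]!r}"
                    )
                break

    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        pssm = pssm_lookup.get(entry.id) if pssm_lookup else None
        seq = sanitize_sequence(entry.id, str(entry.seq), pssm=pssm)
        label = labels.get(entry.id) if labels else None
        records.append(ProteinRecord(id=entry.id, sequence=seq, label=label))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    return records


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (id, class index) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"],
                     dtype={"id": str})
    if df.empty:
        raise ValueError(f"{path}: empty label table")
    return dict(zip(df["id"], df["label"].astype(int)))


def write_labels(labels: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(labels), "label": [labels[k] for k in labels]}
    ).to_csv(path, sep="\t", header=False, index=False)


def parse_psiblast_pssm(
    path: str | Path,
    protein_id: str | None = None,
    expected_sequence: str | None = None,
) -> RawPSSM:
    """Parse a PSI-BLAST ASCII profile, returning the 20 score columns.

    Rows are returned in position order 1..L.  Residue letters are retained
    for cross-checking; if ``expected_sequence`` is given, the first
    disagreement is logged as a warning (1-based position).
    """
    path = Path(path)
    scores: list[list[int]] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if len(tokens) < 2:
                continue
            # Data rows start with a position index followed by a residue letter.
            if not tokens[0].lstrip("-").isdigit():
                continue
            if not (len(tokens[1]) == 1 and tokens[1].isalpha()):
                continue
            fields = tokens[2:]
            # 20 = bare score block; 40 = scores + percentages; 42 adds the
            # two per-position statistics NCBI appends.
            if len(fields) not in (20, 40, 42):
                raise ValueError(
                    f"{path}: line {lineno}: expected 20 or 40 numeric fields "
                    f"in profile row, got {len(fields)}"
                )
            try:
                row = [int(v) for v in fields[:20]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer score field"
                ) from exc
            scores.append(row)
            residues.append(tokens[1].upper())
    if not scores:
        raise ValueError(f"{path}: no profile rows found")

    residue_str = "".join(residues)
    if expected_sequence is not None and residue_str != expected_sequence.upper():
        for pos0, (a, b) in enumerate(zip(residue_str, expected_sequence.upper())):
            if a != b:
                logger.warning(
                    "profile %s: residue column disagrees with sequence at "
                    "position %d (%r vs %r)", path, pos0 + 1, a, b,
                )
                break
        else:
            logger.warning(
                "profile %s: residue column length %d differs from sequence "
                "length %d", path, len(residue_str), len(expected_sequence),
            )

    pid = protein_id if protein_id is not None else path.stem
    return RawPSSM(protein_id=pid, scores=np.array(scores, dtype=int),
                   residues=residue_str)


def sigmoid_normalize(p: RawPSSM) -> NormPSSM:
    """Map each log-odds score x to 1/(1 + exp(-x)), elementwise."""
    return NormPSSM(protein_id=p.protein_id, values=expit(p.scores.astype(float)))
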