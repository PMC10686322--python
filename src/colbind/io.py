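"""Sequence I/O, the antisense-peptide utility and a seedable fixture generator."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ColbindError
from .scale import CANONICAL_RESIDUES

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "antisense_peptide",
    "random_sequence",
    "read_accessibility",
]

_NUCLEOTIDES = set("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    kind: str  # "protein" | "nucleotide"

    def __post_init__(self) -> None:
        if self.kind == "protein":
            for i, letter in enumerate(self.residues, start=1):
                if letter not in CANONICAL_RESIDUES:
                    raise ColbindError(
                        f"record {self.id!r}: non-canonical residue "
                        f"{letter!r} at position {i}"
                    )
        elif self.kind == "nucleotide":
            for i, letter in enumerate(self.residues, start=1):
                if letter not in _NUCLEOTIDES | {"U"}:
                    raise ColbindError(
                        f"record {self.id!r}: invalid nucleotide "
                        f"{letter!r} at position {i}"
                    )
        else:
            raise ColbindError(f"unknown sequence kind {self.kind!r}")


def read_fasta(path, kind: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated records (upper-cased, order kept)."""
    path = Path(path)
    try:
        records = [
            SequenceRecord(id=rec.id, residues=str(rec.seq).strip().upper(), kind=kind)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ColbindError:
        raise
    except ValueError:
        records = []
    if not records:
        # empty or headerless input; report the first offending line
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if line.strip():
                raise ColbindError(
                    f"{path}: line {lineno}: expected a FASTA header ('>')"
                )
        raise ColbindError(f"{path}: line 1: empty FASTA file")
    return records


def antisense_peptide(nt: str, mode: str = "reverse_complement") -> str:
    """Translate the complementary strand of a coding sequence.

    ``reverse_complement`` (default) reverse-complements the full sequence
    and translates 5'->3' - the pairing by which collagen's GPQGLLG coding
    region yields the antisense peptide TKKTLRT.  ``direct_complement``
    complements base-wise without reversing.  U is accepted and mapped to T.
    """
    nt = nt.strip().upper().replace("U", "T")
    bad = [b for b in nt if b not in _NUCLEOTIDES]
    if bad:
        raise ColbindError(f"invalid nucleotide {bad[0]!r} in input")
    if len(nt) % 3 != 0:
        raise ColbindError(
            f"nucleotide length {len(nt)} is not divisible by 3"
        )
    if mode == "reverse_complement":
        coding = Seq(nt).reverse_complement()
    elif mode == "direct_complement":
        coding = Seq(nt).complement()
    else:
        raise ColbindError(f"unknown mode {mode!r}")
    protein = str(coding.translate())
    if "*" in protein:
        i = protein.index("*")
        codon = str(coding)[3 * i : 3 * i + 3]
        raise ColbindError(f"stop codon {codon} at codon {i + 1} of complement strand")
    return protein


def random_sequence(
    length: int,
    weights: dict[str, float] | None = None,
    seed: int | None = None,
    record_id: str = "random",
) -> SequenceRecord:
    """Reproducible random protein sequence drawn per composition weights."""
    if length < 3:
        raise ColbindError("length must be >= 3")
    alphabet = list(CANONICAL_RESIDUES)
    if weights is None:
        p = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        w = np.array([float(weights.get(a, 0.0)) for a in alphabet])
        if (w < 0).any() or w.sum() == 0:
            raise ColbindError("weights must be non-negative and not all zero")
        p = w / w.sum()
    rng = np.random.default_rng(seed)
    letters = rng.choice(alphabet, size=length, p=p)
    return SequenceRecord(id=record_id, residues="".join(letters), kind="protein")


def read_accessibility(path) -> dict[int, float]:
    """Two-column TSV (1-based target position, weight in [0, 1]) -> dict."""
    weights: dict[int, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ColbindError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        try:
            pos, w = int(parts[0]), float(parts[1])
        except ValueError:
            raise ColbindError(f"{path}: line {lineno}: cannot parse position/weight") from None
        if not 0.0 <= w <= 1.0:
            raise ColbindError(f"{path}: line {lineno}: weight {w} outside [0, 1]")
        weights[pos] = w
    if not weights:
        raise ColbindError(f"{path}: no accessibility entries found")
    return weights
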