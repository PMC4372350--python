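"""Peptide/protein sequence container and FASTA I/O.

Sequences are kept as plain strings over the 20-letter amino-acid alphabet.
Nonstandard one-letter codes (B, J, O, U, Z, and lowercase input) are
normalized on construction: case is folded to upper and ambiguous/rare codes
are mapped to ``X``.  Sequences containing ``X`` remain parseable and
printable but are excluded from core determination downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids, alphabetical one-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_ALPHABET_SET = frozenset(ALPHABET)

#: Nonstandard codes collapsed to the unknown-residue symbol.
NONSTANDARD = {"B": "X", "J": "X", "O": "X", "U": "X", "Z": "X", "X": "X"}

_VALID_RE = re.compile(r"^[A-Z]+$")


class SequenceAlphabetError(ValueError):
    """Raised when a residue string contains characters outside A-Z."""


@dataclass(frozen=True)
class AminoAcidSequence:
    """An identified peptide or protein sequence.

    Parameters
    ----------
    id
        Sequence identifier (FASTA header up to first whitespace).
    residues
        Residue string; normalized to uppercase with nonstandard letters
        mapped to ``X``.
    description
        Free-text description (remainder of the FASTA header).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        raw = self.residues.upper().replace("*", "").replace("-", "")
        if not raw:
            raise SequenceAlphabetError(f"{self.id}: empty residue string")
        if not _VALID_RE.match(raw):
            bad = sorted(set(raw) - set("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
            raise SequenceAlphabetError(f"{self.id}: invalid characters {bad}")
        norm = "".join(NONSTANDARD.get(c, c) for c in raw)
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_standard(self) -> bool:
        """True if every residue is one of the 20 canonical amino acids."""
        return all(c in _ALPHABET_SET for c in self.residues)


def read_fasta(handle: TextIO | str) -> list[AminoAcidSequence]:
    """Read a multi-FASTA file into a list of :class:`AminoAcidSequence`."""
    out = []
    for rec in SeqIO.parse(handle, "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(AminoAcidSequence(id=rec.id, residues=str(rec.seq), description=desc))
    return out


def write_fasta(seqs: Iterable[AminoAcidSequence], handle: TextIO | str) -> None:
    """Write sequences as multi-FASTA (60-column wrapped)."""
    records = (
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    )
    SeqIO.write(records, handle, "fasta")


def iter_windows(residues: str, size: int) -> Iterator[tuple[int, str]]:
    """Yield ``(start, window)`` for every full-length window of ``size``."""
    for i in range(len(residues) - size + 1):
        yield i, residues[i : i + size]
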