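"""Core sequence model: normalised DNA/RNA strings, IUPAC matching, strand
operations and FASTA I/O.

All user-facing coordinates throughout the toolkit are 1-based inclusive.
Sequences are stored internally in the T-alphabet (RNA ``U`` is mapped to
``T`` on input) so that RNA motifs can be matched directly against DNA
3'UTR sequences; the original alphabet is kept on the record so reports can
be rendered in the caller's letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, ContractError, FastaFormatError

#: IUPAC degeneracy sets over the T-alphabet.  ``N`` matches any concrete
#: base; an ``N`` in a *sequence body* never matches a concrete pattern
#: position (handled by the matcher, not by this table).
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: Characters allowed in plain sequence bodies (degenerate codes other than
#: N are reserved for primers/motifs, which use :func:`iupac_match`).
_BODY_ALPHABET = frozenset("ACGTUN")


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified, case-normalised nucleotide sequence.

    ``residues`` is always over {A,C,G,T,N}; ``source_alphabet`` records
    whether the input was given as DNA or RNA so positions found in the
    T-alphabet can be reported back in the caller's letters.
    """

    id: str
    residues: str
    source_alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence id must be non-empty")
        if self.source_alphabet not in ("DNA", "RNA"):
            raise ContractError(f"unknown alphabet {self.source_alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive interval [start, end]."""
        if not 1 <= start <= end <= len(self.residues):
            raise ContractError(
                f"interval [{start},{end}] outside sequence {self.id!r} "
                f"of length {len(self.residues)}"
            )
        return self.residues[start - 1 : end]

    def as_source_alphabet(self, residues: str | None = None) -> str:
        """Render residues (default: whole sequence) in the source alphabet."""
        s = self.residues if residues is None else residues
        return s.replace("T", "U") if self.source_alphabet == "RNA" else s


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ContractError(f"invalid interval [{self.start},{self.end}]")
        if self.strand not in "+-":
            raise ContractError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def normalise(raw: str, alphabet: str = "DNA", seq_id: str = "seq") -> NucleotideSequence:
    """Normalise a raw string into a :class:`NucleotideSequence`.

    Whitespace is stripped, case raised and RNA ``U`` mapped to ``T``.
    Degenerate codes other than ``N`` are rejected in sequence bodies (the
    position reported is 1-based over the whitespace-stripped input).
    """
    if alphabet not in ("DNA", "RNA"):
        raise ContractError(f"alphabet must be DNA or RNA, got {alphabet!r}")
    stripped = "".join(raw.split()).upper()
    if not stripped:
        raise AlphabetError("empty sequence")
    for i, ch in enumerate(stripped, start=1):
        if ch not in _BODY_ALPHABET:
            raise AlphabetError(f"invalid character {ch!r} at position {i}")
    return NucleotideSequence(seq_id, stripped.replace("U", "T"), alphabet)


def iupac_match(pattern: str, window: str) -> bool:
    """True iff ``window`` lies in the degeneracy set of ``pattern`` at
    every position.

    Both strings are interpreted in the T-alphabet (``U`` accepted and
    mapped).  ``N`` in the *pattern* matches any concrete base; ``N`` in the
    *window* only matches a pattern ``N``.
    """
    if len(pattern) != len(window):
        raise ContractError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    p = pattern.upper().replace("U", "T")
    w = window.upper().replace("U", "T")
    for pc, wc in zip(p, w):
        if pc not in IUPAC:
            raise AlphabetError(f"invalid IUPAC code {pc!r} in pattern")
        if wc == "N":
            if pc != "N":
                return False
        elif wc not in IUPAC[pc]:
            return False
    return True


def find_iupac(pattern: str, subject: str) -> list[int]:
    """1-based start positions of all (possibly overlapping) degenerate
    matches of ``pattern`` in ``subject``."""
    m = len(pattern)
    return [
        i + 1
        for i in range(len(subject) - m + 1)
        if iupac_match(pattern, subject[i : i + m])
    ]


def complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)


def reverse_complement(seq: NucleotideSequence | str) -> NucleotideSequence | str:
    """Watson-Crick reverse complement; an involution on DNA strings."""
    if isinstance(seq, str):
        return complement(seq)[::-1]
    if seq.source_alphabet != "DNA":
        raise ContractError("reverse_complement is defined for DNA sequences")
    return NucleotideSequence(seq.id, complement(seq.residues)[::-1], "DNA")


def read_fasta(path: str | Path, alphabet: str = "DNA") -> list[NucleotideSequence]:
    """Read a multi-record FASTA into normalised sequences, in file order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[NucleotideSequence] = []
    for rec in records:
        if not rec.id:
            raise FastaFormatError(f"record with blank id in {path}")
        if rec.id in seen:
            raise FastaFormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(normalise(str(rec.seq), alphabet=alphabet, seq_id=rec.id))
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def cpg_positions(seq: NucleotideSequence | str) -> list[int]:
    """1-based positions of the C of every CpG dinucleotide."""
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq
    return [i + 1 for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"]
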