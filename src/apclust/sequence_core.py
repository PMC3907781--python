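"""Alphabets, sequences and the indexed data space.

The data space is an ordered set of unaligned sequences over a finite
residue alphabet: the 20 amino acids for protein families, or the 26
Latin letters for worked text examples.  All positional conventions are
1-based and inclusive — the character at position 13 of a length-29
sequence is ``char_at(S, k, 13)`` — because occurrence coordinates are
reported to users in that convention.

Two reserved symbols never belong to the alphabet itself: ``'-'`` (an
alignment gap interior to a pattern) and ``'*'`` (a don't-care flank in
an aligned cluster).  They appear only downstream, in aligned rows.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

PROTEIN_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"
TEXT_SYMBOLS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

GAP = "-"
WILDCARD = "*"


@dataclass(frozen=True)
class Alphabet:
    """A finite, ordered residue alphabet.

    The gap and wildcard symbols are structural markers used by aligned
    clusters; they are deliberately excluded from ``symbols``.
    """

    symbols: tuple[str, ...]
    gap_symbol: str = GAP
    wildcard_symbol: str = WILDCARD

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValidationError("an alphabet needs at least two symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("alphabet symbols must be unique")
        for s in self.symbols:
            if len(s) != 1:
                raise ValidationError(f"alphabet symbol {s!r} is not a single character")
        if self.gap_symbol in self.symbols or self.wildcard_symbol in self.symbols:
            raise ValidationError("gap/wildcard symbols may not be alphabet members")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, ch: str) -> bool:
        return ch in self._symbol_set()

    def _symbol_set(self) -> frozenset[str]:
        # cached on the instance despite frozen dataclass
        cached = self.__dict__.get("_cache")
        if cached is None:
            cached = frozenset(self.symbols)
            object.__setattr__(self, "_cache", cached)
        return cached

    @classmethod
    def protein(cls) -> "Alphabet":
        """The 20 standard amino acids."""
        return cls(tuple(PROTEIN_SYMBOLS))

    @classmethod
    def text(cls) -> "Alphabet":
        """The 26 Latin letters (upper case), used by the worked examples."""
        return cls(tuple(TEXT_SYMBOLS))

    @classmethod
    def from_string(cls, symbols: str) -> "Alphabet":
        return cls(tuple(symbols))


@dataclass(frozen=True)
class Sequence:
    """One input sequence with its dense 1-based index ``k`` in the data space."""

    id: str
    index: int
    residues: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"sequence index must be positive, got {self.index}")

    def __len__(self) -> int:
        return len(self.residues)

    def char_at(self, j: int) -> str:
        """Residue at 1-based position ``j``."""
        if not 1 <= j <= len(self.residues):
            raise IndexError(
                f"position {j} out of range for sequence {self.id!r} of length {len(self.residues)}"
            )
        return self.residues[j - 1]


@dataclass(frozen=True)
class SequenceSet:
    """The ordered data space S = {s^1, ..., s^|S|}."""

    sequences: tuple[Sequence, ...]

    def __post_init__(self) -> None:
        for pos, seq in enumerate(self.sequences, start=1):
            if seq.index != pos:
                raise ValidationError(
                    f"sequence indices must be dense 1..|S|; found {seq.index} at slot {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __bool__(self) -> bool:
        return bool(self.sequences)

    def by_index(self, k: int) -> Sequence:
        if not 1 <= k <= len(self.sequences):
            raise IndexError(f"sequence index {k} out of range 1..{len(self.sequences)}")
        return self.sequences[k - 1]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def checksum(self) -> str:
        """SHA-256 of a canonical serialization; used for consistency checks."""
        h = hashlib.sha256()
        for seq in self.sequences:
            h.update(seq.id.encode())
            h.update(b"\0")
            h.update(seq.residues.encode())
            h.update(b"\n")
        return h.hexdigest()

    @classmethod
    def from_strings(
        cls,
        strings: Iterable[str],
        ids: Iterable[str] | None = None,
        alphabet: Alphabet | None = None,
        permissive: bool = False,
    ) -> "SequenceSet":
        strings = list(strings)
        if ids is None:
            ids = [f"s{k}" for k in range(1, len(strings) + 1)]
        seqs = []
        for k, (sid, raw) in enumerate(zip(ids, strings), start=1):
            residues = raw.upper()
            if alphabet is not None:
                residues = _validate_residues(sid, residues, alphabet, permissive)
            seqs.append(Sequence(id=sid, index=k, residues=residues))
        return cls(tuple(seqs))


def _validate_residues(seq_id: str, residues: str, alphabet: Alphabet, permissive: bool) -> str:
    """Upper-case and validate a residue string against the alphabet.

    Strict mode rejects any out-of-alphabet character, naming the sequence
    and 1-based position.  Permissive mode keeps unknown characters in
    place (preserving coordinates); downstream pattern enumeration skips
    any window containing them, so they behave as inert positions.
    """
    residues = residues.upper()
    if permissive:
        return residues
    for j, ch in enumerate(residues, start=1):
        if ch not in alphabet:
            raise ValidationError(
                f"sequence {seq_id!r} holds out-of-alphabet character {ch!r} at position {j}"
            )
    return residues


def read_fasta(path: str | Path, alphabet: Alphabet, permissive: bool = False) -> SequenceSet:
    """Read a multi-record FASTA file into a SequenceSet, preserving file order.

    Indices k are assigned by order of appearance.  Residues are upper-cased;
    out-of-alphabet residues raise :class:`ValidationError` unless
    ``permissive`` is set.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.strip():
                raise ParseError(f"{path}: line {lineno}: expected FASTA header '>', got {line[:30]!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    seqs = []
    for k, rec in enumerate(records, start=1):
        residues = _validate_residues(rec.id, str(rec.seq), alphabet, permissive)
        seqs.append(Sequence(id=rec.id, index=k, residues=residues))
    return SequenceSet(tuple(seqs))


def write_fasta(S: SequenceSet, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq.residues), id=seq.id, description="") for seq in S
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_text(path: str | Path, alphabet: Alphabet, permissive: bool = False) -> SequenceSet:
    """Read the plain one-sequence-per-line format used by the text examples."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    strings = [ln for ln in lines if ln]
    return SequenceSet.from_strings(strings, alphabet=alphabet, permissive=permissive)


def write_text(S: SequenceSet, path: str | Path) -> None:
    Path(path).write_text("".join(seq.residues + "\n" for seq in S))


def char_at(S: SequenceSet, k: int, j: int) -> str:
    """The residue s^k_j under 1-based indexing."""
    return S.by_index(k).char_at(j)


def window_count(S: SequenceSet, n: int, mode: str = "windows") -> int:
    """Number N of length-n placements in the data space.

    ``mode="windows"`` (default) counts the exact number of Bernoulli
    trials of the i.i.d. occurrence model: N = sum_k max(0, |s^k| - n + 1).
    ``mode="total"`` returns the total residue count sum_k |s^k| instead,
    for comparison with the looser convention.
    """
    if n < 1:
        raise ValidationError(f"window length must be >= 1, got {n}")
    if mode == "total":
        return S.total_length
    if mode != "windows":
        raise ValidationError(f"unknown window count mode {mode!r}")
    return sum(max(0, len(seq) - n + 1) for seq in S)
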