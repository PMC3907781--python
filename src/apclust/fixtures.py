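"""Worked-example inputs and a seeded synthetic-data generator.

The text example embeds English words into i.i.d. uniform background
letters over the 26-letter alphabet: a ten-sequence set carrying HELLO
and MELLOW five times each, and a six-word cluster (BELLOW, MELLOW,
HELLO, BALLS, BALKS, HALS) whose alignment exercises gaps and wildcard
flanks.  ``generate_embedded`` reproduces the same construction at any
scale — by default six words embedded five times each across thirty
sequences — and records every placement in a ledger so recovery can be
verified exactly.

Case in the worked examples is purely visual (lower-case background,
upper-case embedded words); sequences are normalized to upper case so it
carries no information.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError
from .sequence_core import Alphabet, Sequence, SequenceSet

# The ten-sequence worked example (lower-case background, upper-case planted words).
_TABLE1_STRINGS = (
    "bdxejrtewkwkHELLOkcmstsjavtpi",
    "nfixtHELLOuzdovcaaxnkjfjcvwk",
    "dimtndvkjmkHELLObkcmstsj",
    "tzhgarzofdHELLOpwkxmc",
    "tyjxjqnyHELLOwmopemlqfgptnwnq",
    "kntywtoaxMELLOWbtiasycma",
    "jilxchitivMELLOWriiiweyfzgvuyaa",
    "hmlzvMELLOWorgfeb",
    "xhmlzvqgcanyMELLOWgbfj",
    "vqgcanyffcMELLOWvcnsnjvalbdvr",
)

_TABLE2_WORDS = ("BELLOW", "MELLOW", "HELLO", "BALLS", "BALKS", "HALS")

_HELLO_EXAMPLE = "aaaaaaaaaaaaHELLOaaaaaaaaaaaa"


def ten_sequence_example() -> SequenceSet:
    """The ten-sequence text example, indices 1-10, upper-cased."""
    return SequenceSet.from_strings(_TABLE1_STRINGS, alphabet=Alphabet.text())


def hello_example_sequence() -> Sequence:
    """The 29-character single-sequence example with 'H' at position 13."""
    return Sequence(id="s1", index=1, residues=_HELLO_EXAMPLE.upper())


def six_example_words() -> list[str]:
    """The six words whose aligned cluster is the canonical 6x6 example."""
    return list(_TABLE2_WORDS)


@dataclass(frozen=True)
class Placement:
    word: str
    seq_index: int
    start: int  # 1-based

    @property
    def end(self) -> int:
        return self.start + len(self.word) - 1


@dataclass(frozen=True)
class EmbeddingLedger:
    """Ground truth of a synthetic run: which word went where."""

    seed: int
    words: tuple[str, ...]
    placements: tuple[Placement, ...]
    alphabet: Alphabet

    def verify(self, S: SequenceSet) -> bool:
        """Every placement's window must equal its word exactly."""
        return all(
            S.by_index(p.seq_index).residues[p.start - 1 : p.end] == p.word
            for p in self.placements
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "words": list(self.words),
                "placements": [[p.word, p.seq_index, p.start] for p in self.placements],
            },
            sort_keys=True,
            indent=0,
        )


def _place_in_sequence(
    rng: random.Random, length: int, word_len: int, occupied: list[tuple[int, int]]
) -> int | None:
    """A uniformly chosen 0-based start not overlapping occupied intervals."""
    free = [
        s
        for s in range(length - word_len + 1)
        if all(s + word_len <= a or s >= b for a, b in occupied)
    ]
    if not free:
        return None
    return rng.choice(free)


def generate_embedded(
    words: list[str] | None = None,
    n_sequences: int = 30,
    embeds_per_word: int = 5,
    length_range: tuple[int, int] = (20, 31),
    alphabet: Alphabet | None = None,
    seed: int = 0,
) -> tuple[SequenceSet, EmbeddingLedger]:
    """Embed each word ``embeds_per_word`` times into i.i.d. uniform background.

    Words are placed at uniformly chosen, mutually non-overlapping
    positions; the assignment of embeddings to sequences is random when
    sequences outnumber embeddings and round-robin otherwise.  The output
    is byte-reproducible for a fixed seed.
    """
    alphabet = alphabet or Alphabet.text()
    words = [w.upper() for w in (words if words is not None else six_example_words())]
    for w in words:
        if not w:
            raise ValidationError("embedded words must be non-empty")
        for ch in w:
            if ch not in alphabet:
                raise ValidationError(f"word {w!r} is not over the alphabet")
    lmin, lmax = length_range
    if lmin > lmax or lmin < 1:
        raise ValidationError(f"bad length range {length_range}")
    if words and max(len(w) for w in words) > lmin:
        raise ValidationError("length_range must accommodate the longest word")
    if n_sequences < 1:
        raise ValidationError("need at least one sequence")

    rng = random.Random(seed)
    lengths = [rng.randint(lmin, lmax) for _ in range(n_sequences)]
    chars = [[rng.choice(alphabet.symbols) for _ in range(L)] for L in lengths]

    embeds = [w for w in words for _ in range(embeds_per_word)]
    rng.shuffle(embeds)
    if len(embeds) <= n_sequences:
        targets = rng.sample(range(n_sequences), len(embeds))
    else:
        targets = [i % n_sequences for i in range(len(embeds))]

    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_sequences)}
    placements = []
    for word, tgt in zip(embeds, targets):
        start0 = _place_in_sequence(rng, lengths[tgt], len(word), occupied[tgt])
        if start0 is None:
            raise ValidationError(
                f"infeasible packing: no room for {word!r} in sequence {tgt + 1}"
            )
        occupied[tgt].append((start0, start0 + len(word)))
        chars[tgt][start0 : start0 + len(word)] = list(word)
        placements.append(Placement(word=word, seq_index=tgt + 1, start=start0 + 1))

    S = SequenceSet.from_strings(["".join(c) for c in chars], alphabet=alphabet)
    ledger = EmbeddingLedger(
        seed=seed,
        words=tuple(words),
        placements=tuple(sorted(placements, key=lambda p: (p.seq_index, p.start))),
        alphabet=alphabet,
    )
    assert ledger.verify(S)
    return S, ledger
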