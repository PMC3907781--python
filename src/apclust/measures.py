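"""Scoring of aligned pattern clusters.

Four quantities describe an APC:

* **Coverage** — the number of distinct input sequences carrying at least
  one occurrence of a member pattern (the occurrence-window count is kept
  as a separate field, never conflated).
* **Quality (Q)** — one minus the mean normalized column entropy computed
  from the *member rows*; Q = 1 means every aligned column is a single
  symbol, i.e. a fully conserved cluster.
* **Standard Residual** — (o - e)/sqrt(e), comparing the observed window
  count o = |D(C)| against the expectation e of an i.i.d. uniform column
  model: e = N * prod_j Pr(c_j), with Pr(c_j) = d_j / |Sigma| for a column
  holding d_j distinct residues.
* **Redundancy (R1)** — one minus the normalized column entropy computed
  from the *induced data* D(C), the actual occurrence windows; R1 = 1
  flags a column conserved in the data space (e.g. a binding residue).

Entropies are normalized by taking logarithms in base |Sigma| (20 for
protein, 26 for the text examples), so an equiprobable column over the
alphabet scores exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from .apc_clustering import APC, _is_residue
from .errors import DegenerateModelError, StateError, ValidationError
from .sequence_core import Alphabet, SequenceSet, window_count

Window = tuple[int, int, int]  # (sequence index, start, end), all 1-based


@dataclass(frozen=True)
class ColumnProfile:
    """Symbol distribution of one aligned column.

    ``source`` records whether counts come from the m member rows
    (gaps/wildcards counted as symbols — they carry alignment information)
    or from the induced occurrence windows (residues only).
    """

    index: int
    counts: tuple[tuple[str, int], ...]
    source: str  # "member-rows" | "induced-data"

    @property
    def total(self) -> int:
        return sum(c for _, c in self.counts)

    def probabilities(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            raise DegenerateModelError(f"column {self.index} profile is empty")
        return {ch: c / total for ch, c in self.counts}


def member_column_profile(C: APC, j: int) -> ColumnProfile:
    """Column distribution over the m member rows, '-'/'*' included."""
    counts = C.column_symbol_counts(j)
    return ColumnProfile(index=j, counts=tuple(sorted(counts.items())), source="member-rows")


def _induced_windows(C: APC) -> dict[Window, "object"]:
    """Deduplicated occurrence windows of all members, keyed to the first
    member row that induces each window."""
    windows: dict[Window, object] = {}
    for ap in C.members:
        if ap.source.occurrences is None:
            raise StateError(
                f"member pattern {ap.source.string!r} carries no occurrence list"
            )
        for occ in ap.source.occurrences:
            windows.setdefault(occ.window(), ap)
    return windows


def induced_data_apc(C: APC, S: SequenceSet) -> frozenset[Window]:
    """D(C): the union of the members' occurrence windows, as a set."""
    return frozenset(_induced_windows(C))


def induced_column_profile(C: APC, S: SequenceSet, j: int) -> ColumnProfile:
    """Column distribution counted from the induced windows D(C).

    Each deduplicated window contributes the residue its row places at
    column j (windows are exact copies of their pattern, so the row
    character equals the sequence character); rows with '-'/'*' at j
    contribute nothing — induced windows contain only residues.
    """
    counts: dict[str, int] = {}
    for window, ap in _induced_windows(C).items():
        ch = ap.row[j - 1]
        if _is_residue(ch):
            counts[ch] = counts.get(ch, 0) + 1
    return ColumnProfile(index=j, counts=tuple(sorted(counts.items())), source="induced-data")


def coverage(C: APC, S: SequenceSet) -> int:
    """Number of distinct input sequences covered by the APC."""
    return len({k for (k, _, _) in _induced_windows(C)})


def column_entropy(profile: ColumnProfile, base_size: int) -> float:
    """Shannon entropy in base ``base_size``, clipped to [0, 1].

    The base equals the alphabet size of the run, so a column uniform over
    the whole alphabet scores exactly 1; member-row profiles can hold up
    to two extra structural symbols, hence the clip.
    """
    if base_size < 2:
        raise ValidationError("entropy base must be >= 2")
    probs = profile.probabilities().values()
    h = -sum(p * math.log(p) for p in probs if p > 0) / math.log(base_size)
    return min(h, 1.0)


def quality(C: APC, base_size: int) -> float:
    """Q = 1 - mean column entropy over member rows."""
    n = C.width
    entropies = [column_entropy(member_column_profile(C, j), base_size) for j in range(1, n + 1)]
    return 1.0 - sum(entropies) / n


def null_column_probability(C: APC, j: int, alphabet: Alphabet) -> float:
    """Pr(c_j) under the i.i.d. null: d distinct residues give d/|Sigma|.

    A column containing '*' matches any symbol (probability 1); '-' counts
    as one additional way to match, capped at 1.
    """
    counts = C.column_symbol_counts(j)
    if alphabet.wildcard_symbol in counts:
        return 1.0
    d = sum(1 for ch in counts if _is_residue(ch))
    if alphabet.gap_symbol in counts:
        d += 1
    return min(d / alphabet.size, 1.0)


def expected_occurrences_apc(
    C: APC,
    S: SequenceSet,
    alphabet: Alphabet,
    count_mode: str = "windows",
) -> float:
    """e = N * prod_j Pr(c_j); N counts length-n placements, where n is the
    number of columns carrying at least one residue (pure '*' flank columns
    are presentation padding)."""
    residue_cols = [
        j
        for j in range(1, C.width + 1)
        if any(_is_residue(ch) for ch in C.column(j))
    ]
    n_eff = len(residue_cols)
    if n_eff == 0:
        raise DegenerateModelError("APC has no residue-bearing column")
    e = float(window_count(S, n_eff, mode=count_mode))
    for j in residue_cols:
        e *= null_column_probability(C, j, alphabet)
    return e


def standard_residual_apc(
    C: APC,
    S: SequenceSet,
    alphabet: Alphabet,
    residual_denominator: str = "sqrt",
    count_mode: str = "windows",
) -> float:
    """(o - e)/sqrt(e) with o = |D(C)|; denominator switchable to plain e."""
    e = expected_occurrences_apc(C, S, alphabet, count_mode)
    if e <= 0:
        raise DegenerateModelError("expected occurrence count is zero")
    o = len(induced_data_apc(C, S))
    denom = math.sqrt(e) if residual_denominator == "sqrt" else e
    return (o - e) / denom


def redundancy(C: APC, S: SequenceSet, j: int, base_size: int) -> Optional[float]:
    """R1(c_j) = 1 - H(c_j) on the induced-data column profile.

    Returns ``None`` when no induced window places a residue at column j
    (a pure flank for every member), where the measure is undefined.
    """
    profile = induced_column_profile(C, S, j)
    if profile.total == 0:
        return None
    return 1.0 - column_entropy(profile, base_size)


@dataclass(frozen=True)
class ScoredAPC:
    """An APC together with its four measures and per-column redundancy."""

    apc: APC
    coverage: int
    occurrence_count: int
    quality: float
    expected: float
    standard_residual: float
    column_redundancy: tuple[Optional[float], ...]
    data_checksum: str = ""


def score_apc(
    C: APC,
    S: SequenceSet,
    alphabet: Alphabet,
    base_size: int | None = None,
    residual_denominator: str = "sqrt",
    count_mode: str = "windows",
) -> ScoredAPC:
    """Compute all measures of one APC against the data space."""
    base = base_size if base_size is not None else alphabet.size
    return ScoredAPC(
        apc=C,
        coverage=coverage(C, S),
        occurrence_count=len(induced_data_apc(C, S)),
        quality=quality(C, base),
        expected=expected_occurrences_apc(C, S, alphabet, count_mode),
        standard_residual=standard_residual_apc(C, S, alphabet, residual_denominator, count_mode),
        column_redundancy=tuple(
            redundancy(C, S, j, base) for j in range(1, C.width + 1)
        ),
        data_checksum=S.checksum(),
    )
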