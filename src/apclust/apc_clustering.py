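"""The aligned pattern clustering (APC) step.

Discovered patterns are grouped by single-linkage agglomerative clustering.
Each cluster is an Aligned Pattern Cluster (APC): an m x n matrix whose rows
are the member patterns re-expressed over the alphabet plus two structural
symbols — ``'-'`` for an alignment gap interior to a pattern and ``'*'``
for don't-care flank padding.  Stripping both symbols from any row always
reproduces the original pattern string.

Two APCs are compared by a global (Needleman-Wunsch style) alignment of
their column profiles with free end gaps; the pairwise column score is the
profile agreement sum_sigma Pr1(c_i = sigma) * Pr2(c_j = sigma) over
residues.  The similarity reported for clustering is a normalized Hamming
agreement: the fraction of aligned column pairs whose majority-consensus
residues coincide.  A candidate merge must additionally pass two
heuristics: a minimum number of exactly matching columns and a minimum
mean per-column profile agreement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .pattern_discovery import Pattern
from .sequence_core import GAP, WILDCARD

_STRUCTURAL = {GAP, WILDCARD}


def _is_residue(ch: str) -> bool:
    return ch not in _STRUCTURAL


@dataclass(frozen=True)
class AlignedPattern:
    """One row of an APC: a pattern re-expressed in cluster coordinates."""

    source: Pattern
    row: str

    def __post_init__(self) -> None:
        stripped = self.row.replace(GAP, "").replace(WILDCARD, "")
        if stripped != self.source.string:
            raise ValidationError(
                f"row {self.row!r} does not de-align to its source pattern {self.source.string!r}"
            )
        residue_pos = [i for i, ch in enumerate(self.row) if _is_residue(ch)]
        first, last = residue_pos[0], residue_pos[-1]
        for i, ch in enumerate(self.row):
            if i < first or i > last:
                if ch != WILDCARD:
                    raise ValidationError(f"row {self.row!r}: flank position {i} must be '*'")
            elif ch == WILDCARD:
                raise ValidationError(f"row {self.row!r}: '*' may only pad the flanks")


@dataclass(frozen=True)
class APC:
    """An aligned pattern cluster: m member rows of common width n."""

    members: tuple[AlignedPattern, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("an APC needs at least one member")
        widths = {len(m.row) for m in self.members}
        if len(widths) != 1:
            raise ValidationError(f"rows have mixed widths {sorted(widths)}")
        for j in range(1, self.width + 1):
            if not any(_is_residue(m.row[j - 1]) for m in self.members):
                raise ValidationError(f"column {j} holds no residue")

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def width(self) -> int:
        return len(self.members[0].row)

    @property
    def rows(self) -> tuple[str, ...]:
        return tuple(member.row for member in self.members)

    def column(self, j: int) -> str:
        """The j-th (1-based) aligned column, top to bottom."""
        if not 1 <= j <= self.width:
            raise IndexError(f"column {j} out of range 1..{self.width}")
        return "".join(m.row[j - 1] for m in self.members)

    def column_symbol_counts(self, j: int) -> dict[str, int]:
        """Symbol counts of column j over member rows, gaps/wildcards included."""
        counts: dict[str, int] = {}
        for ch in self.column(j):
            counts[ch] = counts.get(ch, 0) + 1
        return counts

    def column_residue_counts(self, j: int) -> dict[str, int]:
        """Residue-only counts of column j over member rows."""
        return {
            ch: c for ch, c in self.column_symbol_counts(j).items() if _is_residue(ch)
        }

    def profile(self, j: int) -> dict[str, float]:
        """Residue probabilities of column j; gaps/wildcards dilute but score 0."""
        return {ch: c / self.m for ch, c in self.column_residue_counts(j).items()}

    def majority_residues(self, j: int) -> frozenset[str]:
        """Residues achieving the maximal count in column j.

        Ties are kept as a set rather than broken arbitrarily: two columns
        "agree" when their majority sets intersect, which keeps the
        Hamming-style similarity symmetric and independent of row order.
        """
        counts = self.column_residue_counts(j)
        best = max(counts.values())
        return frozenset(ch for ch, c in counts.items() if c == best)

    @classmethod
    def from_pattern(cls, p: Pattern) -> "APC":
        return cls(members=(AlignedPattern(source=p, row=p.string),))


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal monotone pairing of two APCs' column systems.

    ``column_map`` pairs 1-based column indices; ``None`` marks a gap on
    that side.  ``score`` is the consensus-agreement similarity in [0, 1];
    ``matched_columns`` counts the exactly agreeing aligned column pairs;
    ``mean_column_agreement`` is the mean profile-agreement over aligned
    pairs, used by the candidate-filter heuristic.
    """

    column_map: tuple[tuple[Optional[int], Optional[int]], ...]
    score: float
    matched_columns: int
    mean_column_agreement: float


@dataclass(frozen=True)
class ClusterConfig:
    """Tunables of the APC step.

    Defaults mirror the settings used for a large protein family run
    (termination 0.8, column distribution 0.8, three overlapping column
    matches); small worked examples typically relax the two scores to 0.3.
    The DP constants are free end gaps (realized as '*' padding) and a
    mild internal gap penalty, which is what reproduces a single interior
    '-' rather than scattered gaps.
    """

    termination_score: float = 0.8
    column_distribution_min: float = 0.8
    min_overlap_matches: int = 3
    gap_penalty: float = -0.5
    end_gap_penalty: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.termination_score <= 1:
            raise ValidationError("termination_score must lie in [0, 1]")
        if self.min_overlap_matches < 1:
            raise ValidationError("min_overlap_matches must be >= 1")


def _profile_agreement(p1: dict[str, float], p2: dict[str, float]) -> float:
    if len(p2) < len(p1):
        p1, p2 = p2, p1
    return sum(pr * p2.get(ch, 0.0) for ch, pr in p1.items())


def align_apcs(C1: APC, C2: APC, config: ClusterConfig | None = None) -> AlignmentResult:
    """Global profile alignment of two APCs' column sequences.

    Needleman-Wunsch over columns with the profile-agreement match score,
    ``gap_penalty`` for interior gaps and ``end_gap_penalty`` (default 0,
    i.e. free) for terminal overhangs.  Traceback tie-breaks are fixed
    (diagonal, then up, then left) so the result is deterministic.
    """
    config = config or ClusterConfig()
    n1, n2 = C1.width, C2.width
    prof1 = [C1.profile(j) for j in range(1, n1 + 1)]
    prof2 = [C2.profile(j) for j in range(1, n2 + 1)]
    s = np.empty((n1, n2))
    for i in range(n1):
        for j in range(n2):
            s[i, j] = _profile_agreement(prof1[i], prof2[j])

    gp, egp = config.gap_penalty, config.end_gap_penalty
    F = np.empty((n1 + 1, n2 + 1))
    F[:, 0] = egp * np.arange(n1 + 1)
    F[0, :] = egp * np.arange(n2 + 1)
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            up = F[i - 1, j] + (egp if j == n2 else gp)
            left = F[i, j - 1] + (egp if i == n1 else gp)
            F[i, j] = max(F[i - 1, j - 1] + s[i - 1, j - 1], up, left)

    # traceback, preferring diagonal, then up, then left
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    i, j = n1, n2
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + s[i - 1, j - 1]:
            pairs.append((i, j))
            i, j = i - 1, j - 1
        elif i > 0 and F[i, j] == F[i - 1, j] + (egp if j in (0, n2) else gp):
            pairs.append((i, None))
            i -= 1
        else:
            pairs.append((None, j))
            j -= 1
    pairs.reverse()
    column_map = tuple(pairs)

    both = [(a, b) for a, b in column_map if a is not None and b is not None]
    matched = sum(
        1 for a, b in both if C1.majority_residues(a) & C2.majority_residues(b)
    )
    score = matched / len(both) if both else 0.0
    mean_agreement = (
        sum(s[a - 1, b - 1] for a, b in both) / len(both) if both else 0.0
    )
    return AlignmentResult(
        column_map=column_map,
        score=score,
        matched_columns=matched,
        mean_column_agreement=mean_agreement,
    )


def similarity(C1: APC, C2: APC, config: ClusterConfig | None = None) -> float:
    """Hamming-style similarity: fraction of aligned column pairs whose
    consensus residues agree, over pairs where both columns hold residues."""
    return align_apcs(C1, C2, config).score


def candidate_filter(
    C1: APC,
    C2: APC,
    config: ClusterConfig,
    result: AlignmentResult | None = None,
) -> bool:
    """Merge-eligibility heuristics: enough exactly matching columns and a
    high enough mean per-column profile agreement."""
    if result is None:
        result = align_apcs(C1, C2, config)
    return (
        result.matched_columns >= config.min_overlap_matches
        and result.mean_column_agreement >= config.column_distribution_min
    )


def _normalize_row(chars: list[str]) -> str:
    """Turn placeholder fills into structural symbols.

    Positions outside a row's own residue span become '*', interior
    non-residues become '-'.  Works on whatever fill characters the merge
    inserted, and re-normalizes inherited symbols consistently.
    """
    residue_pos = [i for i, ch in enumerate(chars) if ch not in _STRUCTURAL and ch != "\0"]
    if not residue_pos:
        raise ValidationError("a merged row lost all its residues")
    first, last = residue_pos[0], residue_pos[-1]
    out = []
    for i, ch in enumerate(chars):
        if ch not in _STRUCTURAL and ch != "\0":
            out.append(ch)
        elif i < first or i > last:
            out.append(WILDCARD)
        else:
            out.append(GAP)
    return "".join(out)


def merge(C1: APC, C2: APC, result: AlignmentResult) -> APC:
    """Merge two APCs into one, re-expressing all rows in the merged
    coordinate system given by ``result.column_map``."""
    for a, b in result.column_map:
        if a is not None and not 1 <= a <= C1.width:
            raise ValidationError("column_map is inconsistent with the first APC")
        if b is not None and not 1 <= b <= C2.width:
            raise ValidationError("column_map is inconsistent with the second APC")

    members = []
    for apc, side in ((C1, 0), (C2, 1)):
        for ap in apc.members:
            chars = []
            for pair in result.column_map:
                idx = pair[side]
                chars.append(ap.row[idx - 1] if idx is not None else "\0")
            members.append(AlignedPattern(source=ap.source, row=_normalize_row(chars)))

    # drop any column left with no residue at all (pure padding)
    width = len(result.column_map)
    keep = [
        j
        for j in range(width)
        if any(_is_residue(m.row[j]) for m in members)
    ]
    if len(keep) != width:
        members = [
            AlignedPattern(source=m.source, row="".join(m.row[j] for j in keep))
            for m in members
        ]
    return APC(members=tuple(members))


def _pair_key(C1: APC, C2: APC) -> tuple[str, str]:
    return tuple(sorted((C1.members[0].row, C2.members[0].row)))


def cluster(patterns: list[Pattern], config: ClusterConfig) -> list[APC]:
    """Single-linkage agglomerative clustering of patterns into APCs.

    Starts from one singleton APC per pattern and repeatedly merges the
    candidate-filtered pair with maximal similarity, until the best
    remaining pair falls below the termination score.  Ties are broken by
    the lexicographically smallest (first-row, first-row) pair, so the
    outcome is deterministic for a fixed input order-free pattern set.
    """
    if not patterns:
        raise ValidationError("cannot cluster an empty pattern list")
    apcs: list[APC] = [APC.from_pattern(p) for p in patterns]
    cache: dict[tuple[APC, APC], AlignmentResult] = {}

    def aligned(a: int, b: int) -> AlignmentResult:
        key = (apcs[a], apcs[b])
        if key not in cache:
            cache[key] = align_apcs(apcs[a], apcs[b], config)
        return cache[key]

    while len(apcs) > 1:
        best: tuple[float, tuple[str, str], int, int] | None = None
        for a, b in itertools.combinations(range(len(apcs)), 2):
            res = aligned(a, b)
            if not candidate_filter(apcs[a], apcs[b], config, res):
                continue
            cand = (-res.score, _pair_key(apcs[a], apcs[b]), a, b)
            if best is None or cand < best:
                best = cand
        if best is None or -best[0] < config.termination_score:
            break
        _, _, a, b = best
        merged = merge(apcs[a], apcs[b], aligned(a, b))
        apcs = [c for idx, c in enumerate(apcs) if idx not in (a, b)] + [merged]
    return apcs
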