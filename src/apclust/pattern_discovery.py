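"""The pattern discovery (PD) step.

Exhaustively enumerates candidate substrings of the data space and prunes
them down to a compact list of statistically significant, delta-closed,
non-induced patterns, each carrying its full occurrence list.

Significance is measured as a standard residual against an order-0 i.i.d.
null: a pattern of length ``l`` is expected ``e0 = N * (1/|Sigma|)^l``
times, where ``N`` is the number of length-``l`` windows in the data
space.  The residual ``(o - e0)/sqrt(e0)`` is the ranking score; the
default acceptance threshold of 3.0 is a conventional ~3-sigma cut.

Redundancy pruning has two parts:

* *delta-closure*: a pattern is dropped when a strict super-string in the
  significant set covers at least a ``delta`` fraction of its occurrences
  (the longer pattern explains the shorter one);
* *non-induced*: a pattern is dropped when its occurrence count is no more
  than chance given its most explanatory surviving sub-pattern, i.e. the
  residual of ``o`` against ``e_cond = occ(q) * (1/|Sigma|)^(|p|-|q|)``
  falls below the significance threshold.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DegenerateModelError, ParseError, StateError, ValidationError
from .sequence_core import Alphabet, SequenceSet, window_count

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Occurrence:
    """One placement of a pattern: sequence index and 1-based start/end."""

    seq_index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.seq_index < 1 or self.start < 1 or self.end < self.start:
            raise ValidationError(f"malformed occurrence {self!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def window(self) -> tuple[int, int, int]:
        return (self.seq_index, self.start, self.end)


@dataclass(frozen=True)
class Pattern:
    """A contiguous string over the alphabet with its occurrence list.

    ``occurrences=None`` means the list was never computed (a bare motif
    string, e.g. one injected for clustering experiments); an empty tuple
    means the pattern genuinely never occurs.  Operations that need the
    induced data raise :class:`StateError` on the former.
    """

    string: str
    occurrences: tuple[Occurrence, ...] | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.string:
            raise ValidationError("pattern string must be non-empty")
        for occ in self.occurrences or ():
            if occ.length != len(self.string):
                raise ValidationError(
                    f"occurrence window length {occ.length} != pattern order {len(self.string)}"
                )

    @property
    def order(self) -> int:
        return len(self.string)

    @property
    def occurrence_count(self) -> int:
        return len(self.occurrences or ())

    @property
    def induced_data(self) -> frozenset[tuple[int, int, int]]:
        """D(p): the set of distinct occurrence windows."""
        if self.occurrences is None:
            raise StateError(f"pattern {self.string!r} carries no occurrence list")
        return frozenset(o.window() for o in self.occurrences)

    def verify_against(self, S: SequenceSet) -> bool:
        """Check every occurrence by direct substring comparison."""
        return all(
            S.by_index(o.seq_index).residues[o.start - 1 : o.end] == self.string
            for o in self.occurrences or ()
        )


@dataclass(frozen=True)
class DiscoveryConfig:
    """Tunables of the PD step.

    ``min_order``/``min_occurrence``/``delta`` follow the reference protein-family runs
    (order 5, occurrence 20, delta 0.9 for a ~300-sequence family);
    ``significance_threshold`` is the residual cut described above.
    """

    min_order: int = 5
    min_occurrence: int = 20
    delta: float = 0.9
    significance_threshold: float = 3.0
    background: str = "uniform"  # "uniform" | "empirical"
    residual_denominator: str = "sqrt"  # "sqrt" | "plain"
    count_mode: str = "windows"  # "windows" | "total"

    def __post_init__(self) -> None:
        if self.min_order < 1:
            raise ValidationError("min_order must be >= 1")
        if self.min_occurrence < 1:
            raise ValidationError("min_occurrence must be >= 1")
        if not 0 < self.delta <= 1:
            raise ValidationError("delta must lie in (0, 1]")
        if self.background not in ("uniform", "empirical"):
            raise ValidationError(f"unknown background {self.background!r}")
        if self.residual_denominator not in ("sqrt", "plain"):
            raise ValidationError(f"unknown residual denominator {self.residual_denominator!r}")


def empirical_frequencies(S: SequenceSet, alphabet: Alphabet) -> dict[str, float]:
    """Per-symbol relative frequencies estimated from the data space."""
    counts = Counter()
    for seq in S:
        counts.update(ch for ch in seq.residues if ch in alphabet)
    total = sum(counts.values())
    if total == 0:
        raise DegenerateModelError("no in-alphabet residues to estimate frequencies from")
    return {sym: counts.get(sym, 0) / total for sym in alphabet.symbols}


def enumerate_candidates(
    S: SequenceSet,
    min_order: int,
    min_occurrence: int,
    alphabet: Alphabet,
) -> list[Pattern]:
    """Every distinct substring of length >= min_order occurring >= min_occurrence times.

    Enumeration proceeds length by length and stops as soon as a length has
    no survivor: support is anti-monotone in length, so no longer substring
    can reach the occurrence floor either.  Windows containing characters
    outside the alphabet (possible under permissive input) are skipped.
    Overlapping occurrences within one sequence all count.
    """
    if not S:
        raise ValidationError("cannot enumerate candidates of an empty data space")
    if min_order < 1 or min_occurrence < 1:
        raise ValidationError("min_order and min_occurrence must be >= 1")

    # prefix counts of out-of-alphabet characters, for O(1) window validity
    bad_prefix: dict[int, list[int]] = {}
    for seq in S:
        pref = [0]
        for ch in seq.residues:
            pref.append(pref[-1] + (0 if ch in alphabet else 1))
        bad_prefix[seq.index] = pref

    patterns: list[Pattern] = []
    length = min_order
    while True:
        occ: dict[str, list[Occurrence]] = {}
        for seq in S:
            residues = seq.residues
            pref = bad_prefix[seq.index]
            for start0 in range(len(residues) - length + 1):
                if pref[start0 + length] - pref[start0]:
                    continue
                sub = residues[start0 : start0 + length]
                occ.setdefault(sub, []).append(
                    Occurrence(seq.index, start0 + 1, start0 + length)
                )
        surviving = {s: o for s, o in occ.items() if len(o) >= min_occurrence}
        if not surviving:
            break
        patterns.extend(
            Pattern(string=s, occurrences=tuple(o)) for s, o in sorted(surviving.items())
        )
        length += 1
    return patterns


def pattern_expected_occurrences(
    p: Pattern,
    S: SequenceSet,
    alphabet: Alphabet,
    background: str = "uniform",
    count_mode: str = "windows",
) -> float:
    """Expected occurrence count e0 of the pattern under the i.i.d. null."""
    for ch in p.string:
        if ch not in alphabet:
            raise ValidationError(f"pattern {p.string!r} holds non-alphabet character {ch!r}")
    n_windows = window_count(S, p.order, mode=count_mode)
    if background == "uniform":
        prob = (1.0 / alphabet.size) ** p.order
    else:
        freqs = empirical_frequencies(S, alphabet)
        prob = math.prod(freqs[ch] for ch in p.string)
    return n_windows * prob


def pattern_standard_residual(
    p: Pattern,
    S: SequenceSet,
    alphabet: Alphabet,
    background: str = "uniform",
    residual_denominator: str = "sqrt",
    count_mode: str = "windows",
) -> float:
    """Standard residual (o - e0)/sqrt(e0) of the observed occurrence count."""
    e0 = pattern_expected_occurrences(p, S, alphabet, background, count_mode)
    if e0 <= 0:
        raise DegenerateModelError(f"expected occurrences of {p.string!r} is zero")
    o = len(p.induced_data)
    denom = math.sqrt(e0) if residual_denominator == "sqrt" else e0
    return (o - e0) / denom


def prune_delta_closed(patterns: list[Pattern], delta: float) -> list[Pattern]:
    """Drop patterns covered by a strict super-string in the (significant) set.

    A pattern p is absorbed when some strict super-string q in the list
    satisfies occ(q) >= delta * occ(p).  Callers pass the already
    significance-filtered list, so every potential absorber has itself
    passed the threshold.  Survivors are returned unchanged.
    """
    if not 0 < delta <= 1:
        raise ValidationError("delta must lie in (0, 1]")
    survivors = []
    for p in patterns:
        absorbed = any(
            q.string != p.string
            and p.string in q.string
            and q.occurrence_count >= delta * p.occurrence_count
            for q in patterns
        )
        if not absorbed:
            survivors.append(p)
    return survivors


def _string_probability(string: str, alphabet: Alphabet, freqs: Mapping[str, float] | None) -> float:
    if freqs is None:
        return (1.0 / alphabet.size) ** len(string)
    # floor avoids a zero expectation for symbols never seen in the data
    return math.prod(max(1e-9, freqs[ch]) for ch in string)


def _conditional_expectation(
    p: Pattern,
    q: Pattern,
    S: SequenceSet,
    alphabet: Alphabet,
    freqs: Mapping[str, float] | None,
    count_mode: str,
) -> float:
    """Expected occurrences of p given that the related pattern q occurred occ(q) times.

    For a sub-pattern q of p, each q occurrence extends to p at the chance
    rate of the extension characters (leftmost embedding of q in p).  For a
    super-pattern q of p, every q occurrence forces one p occurrence and
    the remaining windows produce p at the background rate.
    """
    if q.string in p.string:
        at = p.string.index(q.string)
        extension = p.string[:at] + p.string[at + q.order :]
        return q.occurrence_count * _string_probability(extension, alphabet, freqs)
    if p.string in q.string:
        n_windows = window_count(S, p.order, mode=count_mode)
        chance = _string_probability(p.string, alphabet, freqs)
        return q.occurrence_count + max(0, n_windows - q.occurrence_count) * chance
    raise ValidationError(f"{q.string!r} is neither sub- nor super-pattern of {p.string!r}")


def prune_induced(
    patterns: list[Pattern],
    S: SequenceSet,
    alphabet: Alphabet,
    significance_threshold: float,
    background: str = "uniform",
    residual_denominator: str = "sqrt",
    count_mode: str = "windows",
) -> list[Pattern]:
    """Drop patterns whose occurrence count is explained by a related survivor.

    For each pattern p, the most explanatory proper sub- or super-pattern
    q in the list is the one maximizing the conditional expectation
    e_cond; p is dropped when the residual of its occurrence count against
    e_cond falls below the significance threshold.  The super-pattern
    direction matters when a longer pattern covers slightly less than a
    delta fraction of a shorter one: the shorter pattern's few excess
    occurrences are then tested against chance and usually fail.
    """
    freqs = empirical_frequencies(S, alphabet) if background == "empirical" else None
    survivors = []
    for p in patterns:
        related = [
            q
            for q in patterns
            if q.string != p.string and (q.string in p.string or p.string in q.string)
        ]
        if related:
            e_cond = max(
                _conditional_expectation(p, q, S, alphabet, freqs, count_mode) for q in related
            )
            o = len(p.induced_data)
            denom = math.sqrt(e_cond) if residual_denominator == "sqrt" else e_cond
            if (o - e_cond) / denom < significance_threshold:
                continue
        survivors.append(p)
    return survivors


def discover(
    S: SequenceSet,
    config: DiscoveryConfig,
    alphabet: Alphabet,
    stats: dict | None = None,
) -> list[Pattern]:
    """Full PD pipeline: enumerate, score, filter, delta-close, de-induce.

    Output is sorted by descending significance, ties broken
    lexicographically by pattern string, so the result is deterministic
    for a fixed data space and configuration.  Pass a dict as ``stats``
    to receive the per-stage pattern counts (the pruning funnel).
    """
    candidates = enumerate_candidates(S, config.min_order, config.min_occurrence, alphabet)
    scored = [
        replace(
            p,
            score=pattern_standard_residual(
                p, S, alphabet, config.background, config.residual_denominator, config.count_mode
            ),
        )
        for p in candidates
    ]
    significant = [p for p in scored if p.score >= config.significance_threshold]
    closed = prune_delta_closed(significant, config.delta)
    final = prune_induced(
        closed,
        S,
        alphabet,
        config.significance_threshold,
        config.background,
        config.residual_denominator,
        config.count_mode,
    )
    final = sorted(final, key=lambda p: (-p.score, p.string))
    funnel = {
        "candidates": len(candidates),
        "significant": len(significant),
        "delta_closed": len(closed),
        "non_induced": len(final),
    }
    if stats is not None:
        stats.update(funnel)
    logger.info(
        "PD funnel: %(candidates)d candidates -> %(significant)d significant -> "
        "%(delta_closed)d delta-closed -> %(non_induced)d final",
        funnel,
    )
    return final


# ---------------------------------------------------------------------------
# serialization: TSV table plus JSON occurrence sidecar


def write_patterns(patterns: list[Pattern], tsv_path: str | Path, json_path: str | Path) -> None:
    """Write the pattern table (TSV) and its occurrence sidecar (JSON)."""
    lines = ["pattern\torder\toccurrence_count\tscore"]
    sidecar = {}
    for p in patterns:
        score = "" if p.score is None else repr(p.score)
        lines.append(f"{p.string}\t{p.order}\t{p.occurrence_count}\t{score}")
        sidecar[p.string] = [[o.seq_index, o.start] for o in p.occurrences or ()]
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    Path(json_path).write_text(json.dumps(sidecar, sort_keys=True, indent=0) + "\n")


def read_patterns(tsv_path: str | Path, json_path: str | Path) -> list[Pattern]:
    """Read a pattern table written by :func:`write_patterns`."""
    sidecar = json.loads(Path(json_path).read_text())
    patterns = []
    lines = Path(tsv_path).read_text().splitlines()
    if not lines or lines[0].split("\t")[0] != "pattern":
        raise ParseError(f"{tsv_path}: missing 'pattern' header row")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            string, order, count, score = line.split("\t")
        except ValueError as exc:
            raise ValidationError(f"{tsv_path}: line {lineno}: malformed row") from exc
        occs = tuple(
            Occurrence(k, start, start + len(string) - 1) for k, start in sidecar.get(string, [])
        )
        if len(occs) != int(count):
            raise ValidationError(
                f"{tsv_path}: line {lineno}: occurrence sidecar disagrees with count column"
            )
        patterns.append(Pattern(string=string, occurrences=occs, score=float(score) if score else None))
    return patterns
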