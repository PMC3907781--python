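"""Independent reference implementations used only as test oracles.

Deliberately naive: nested-loop substring census, pairwise containment
scans, and exhaustive enumeration of alignment paths.  These share no
code with the package so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math


def census(strings: list[str], min_order: int, min_occurrence: int) -> dict[str, set]:
    """All substrings of length >= min_order with >= min_occurrence windows.

    O(L^2) nested loops; windows are (1-based sequence index, 1-based start).
    """
    counts: dict[str, set] = {}
    for k, s in enumerate(strings, start=1):
        for i in range(len(s)):
            for j in range(i + min_order, len(s) + 1):
                counts.setdefault(s[i:j], set()).add((k, i + 1))
    return {sub: occ for sub, occ in counts.items() if len(occ) >= min_occurrence}


def brute_force_discover(
    strings: list[str],
    alphabet_size: int,
    min_order: int,
    min_occurrence: int,
    delta: float,
    threshold: float,
) -> set[tuple[str, frozenset]]:
    """Census + significance + delta-closure + conditional-redundancy filters.

    Returns {(pattern string, frozenset of (k, start) windows)}.
    """
    cand = census(strings, min_order, min_occurrence)

    def n_windows(length: int) -> int:
        return sum(max(0, len(s) - length + 1) for s in strings)

    def residual(o: float, e: float) -> float:
        return (o - e) / math.sqrt(e)

    significant = {}
    for sub, occ in cand.items():
        e0 = n_windows(len(sub)) * alphabet_size ** -len(sub)
        if residual(len(occ), e0) >= threshold:
            significant[sub] = occ

    closed = {}
    for sub, occ in significant.items():
        absorbed = any(
            sub != sup and sub in sup and len(soc) >= delta * len(occ)
            for sup, soc in significant.items()
        )
        if not absorbed:
            closed[sub] = occ

    final = set()
    for sub, occ in closed.items():
        e_best = None
        for other, ooc in closed.items():
            if other == sub:
                continue
            if other in sub:
                e = len(ooc) * alphabet_size ** -(len(sub) - len(other))
            elif sub in other:
                e = len(ooc) + max(0, n_windows(len(sub)) - len(ooc)) * alphabet_size ** -len(sub)
            else:
                continue
            if e_best is None or e > e_best:
                e_best = e
        if e_best is not None and residual(len(occ), e_best) < threshold:
            continue
        final.add((sub, frozenset(occ)))
    return final


def enumerate_alignments(n1: int, n2: int):
    """Every monotone complete pairing of columns 1..n1 with 1..n2.

    Yields tuples of (i or None, j or None) pairs, each column used once.
    """

    def rec(i, j):
        if i == n1 and j == n2:
            yield ()
            return
        if i < n1 and j < n2:
            for rest in rec(i + 1, j + 1):
                yield ((i + 1, j + 1),) + rest
        if i < n1:
            for rest in rec(i + 1, j):
                yield ((i + 1, None),) + rest
        if j < n2:
            for rest in rec(i, j + 1):
                yield ((None, j + 1),) + rest

    yield from rec(0, 0)


def alignment_objective(path, match_score, gap_penalty, end_gap_penalty) -> float:
    """DP objective of one alignment path: profile agreements for matched
    pairs, end-gap cost for one-sided pairs in the leading/trailing runs,
    interior gap cost otherwise."""
    one_sided = [idx for idx, (a, b) in enumerate(path) if a is None or b is None]
    lead = 0
    while lead < len(path) and (path[lead][0] is None or path[lead][1] is None):
        lead += 1
    trail = len(path)
    while trail > 0 and (path[trail - 1][0] is None or path[trail - 1][1] is None):
        trail -= 1
    total = 0.0
    for idx, (a, b) in enumerate(path):
        if a is not None and b is not None:
            total += match_score(a, b)
        elif idx < lead or idx >= trail:
            total += end_gap_penalty
        else:
            total += gap_penalty
    return total


def best_alignment_score(C1, C2, gap_penalty=-0.5, end_gap_penalty=0.0) -> float:
    """Maximal objective over all monotone alignments of two small APCs."""

    def match_score(i, j):
        p1, p2 = C1.profile(i), C2.profile(j)
        return sum(pr * p2.get(ch, 0.0) for ch, pr in p1.items())

    return max(
        alignment_objective(path, match_score, gap_penalty, end_gap_penalty)
        for path in enumerate_alignments(C1.width, C2.width)
    )
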