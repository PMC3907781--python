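"""Ranked tables, regex motifs, reduction statistics and annotations.

APCs are presented the way motif databases print them: one PROSITE-like
regular expression per cluster (a bracket class ``[KR]`` where a column
varies), ranked by standard residual.  Conserved columns — redundancy
R1 at or above a threshold, 1.0 by default — can be flagged and labelled
with user-supplied reference residues such as His18 or Met62.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

from .apc_clustering import APC, _is_residue
from .errors import ConsistencyError, ValidationError
from .measures import ScoredAPC
from .sequence_core import SequenceSet


def regex_parts(C: APC, order: str = "frequency") -> list[tuple[int, str]]:
    """Per-column motif pieces: (1-based column index, rendered piece).

    A single distinct residue renders as the letter itself; several render
    as a bracket class ordered by descending member-row frequency, then
    alphabetically (``order="alpha"`` sorts purely alphabetically).
    Columns without any residue are skipped; interior '-' makes the
    residue class optional in occurrence semantics but is not rendered in
    the motif string.
    """
    parts: list[tuple[int, str]] = []
    for j in range(1, C.width + 1):
        counts = C.column_residue_counts(j)
        if not counts:
            continue
        if len(counts) == 1:
            parts.append((j, next(iter(counts))))
            continue
        if order == "frequency":
            ordered = sorted(counts, key=lambda ch: (-counts[ch], ch))
        elif order == "alpha":
            ordered = sorted(counts)
        else:
            raise ValidationError(f"unknown bracket-class order {order!r}")
        parts.append((j, "[" + "".join(ordered) + "]"))
    return parts


def to_regex(C: APC, order: str = "frequency") -> str:
    """PROSITE-style motif string of an APC."""
    return "".join(piece for _, piece in regex_parts(C, order))


@dataclass(frozen=True)
class RankedRow:
    rank: int
    scored: ScoredAPC
    regex: str
    conserved_columns: tuple[int, ...] = ()
    labels: tuple[tuple[int, str], ...] = ()  # (column index, label)


@dataclass(frozen=True)
class RankedTable:
    """Scored APCs sorted by descending standard residual.

    Ties break by descending coverage, then lexicographically by regex;
    the order is therefore total and reproducible.
    """

    rows: tuple[RankedRow, ...]

    def to_tsv(self) -> str:
        lines = ["rank\tregex\tm\tn\tquality\tcoverage\toccurrence_count\tstandard_residual"]
        for row in self.rows:
            sc = row.scored
            lines.append(
                f"{row.rank}\t{row.regex}\t{sc.apc.m}\t{sc.apc.width}\t"
                f"{sc.quality:g}\t{sc.coverage}\t{sc.occurrence_count}\t"
                f"{sc.standard_residual:.2E}"
            )
        return "\n".join(lines) + "\n"

    def to_markdown(self) -> str:
        header = (
            "| rank | APC (as regular expression) | m | n | Quality | Coverage | "
            "Standard Residual | Annotated Columns |"
        )
        rule = "|---|---|---|---|---|---|---|---|"
        lines = [header, rule]
        for row in self.rows:
            sc = row.scored
            flagged = set(row.conserved_columns)
            rendered: list[str] = []
            bold_open = False
            for j, piece in regex_parts(sc.apc):
                if (j in flagged) != bold_open:
                    rendered.append("**")
                    bold_open = not bold_open
                rendered.append(piece)
            if bold_open:
                rendered.append("**")
            labels = ", ".join(label for _, label in row.labels)
            lines.append(
                f"| {row.rank} | {''.join(rendered)} | {sc.apc.m} | {sc.apc.width} | "
                f"{sc.quality:g} | {sc.coverage} | {sc.standard_residual:.2E} | {labels} |"
            )
        return "\n".join(lines) + "\n"


def rank_apcs(scored: list[ScoredAPC]) -> RankedTable:
    """Sort scored APCs into a ranked table (ranks assigned 1..len)."""
    if not scored:
        return RankedTable(rows=())
    checksums = {sc.data_checksum for sc in scored}
    if len(checksums) > 1:
        raise ConsistencyError("scored APCs were computed against different sequence sets")
    ordered = sorted(
        scored,
        key=lambda sc: (-sc.standard_residual, -sc.coverage, to_regex(sc.apc)),
    )
    return RankedTable(
        rows=tuple(
            RankedRow(rank=i, scored=sc, regex=to_regex(sc.apc))
            for i, sc in enumerate(ordered, start=1)
        )
    )


def reduction_stats(pattern_count: int, apc_count: int) -> float:
    """Percent reduction 100 * (patterns - APCs)/patterns, half-up to 2 decimals."""
    if pattern_count <= 0:
        raise ValidationError("pattern_count must be positive")
    if not 0 <= apc_count <= pattern_count:
        raise ValidationError("need 0 <= apc_count <= pattern_count")
    value = Decimal(100 * (pattern_count - apc_count)) / Decimal(pattern_count)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percentage(part: int, whole: int) -> float:
    """Percent share 100 * part/whole with the same half-up rendering."""
    if whole <= 0:
        raise ValidationError("whole must be positive")
    value = Decimal(100 * part) / Decimal(whole)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _column_positions(sc: ScoredAPC, j: int, reference_index: int) -> set[int]:
    """Sequence positions (1-based) that column j occupies in the reference
    sequence, across the member occurrence windows."""
    positions: set[int] = set()
    for ap in sc.apc.members:
        ch = ap.row[j - 1]
        if not _is_residue(ch):
            continue
        offset = sum(1 for c in ap.row[: j - 1] if _is_residue(c))
        for occ in ap.source.occurrences or ():
            if occ.seq_index == reference_index:
                positions.add(occ.start + offset)
    return positions


def annotate_conserved(
    table: RankedTable,
    threshold: float = 1.0,
    annotations: Mapping[int, str] | None = None,
    S: SequenceSet | None = None,
    reference_id: str | None = None,
    reference_index: int | None = None,
) -> RankedTable:
    """Flag columns with R1 >= threshold and attach reference labels.

    ``annotations`` maps 1-based positions in the reference sequence
    (chosen by ``reference_id`` within ``S``, or given directly as
    ``reference_index``) to labels such as "His18".  A label is attached
    to a flagged column when some member occurrence places that column at
    the annotated position.  Annotation positions matching no APC produce
    a warning, not an error.
    """
    if annotations and reference_index is None:
        if S is not None:
            if reference_id is None:
                reference_index = 1
            else:
                matches = [seq.index for seq in S if seq.id == reference_id]
                if not matches:
                    raise ValidationError(f"reference sequence {reference_id!r} not in data space")
                reference_index = matches[0]

    used_positions: set[int] = set()
    rows = []
    for row in table.rows:
        flagged = tuple(
            j
            for j, r1 in enumerate(row.scored.column_redundancy, start=1)
            if r1 is not None and r1 >= threshold
        )
        labels: list[tuple[int, str]] = []
        if annotations and reference_index is not None:
            for j in flagged:
                positions = _column_positions(row.scored, j, reference_index)
                for pos, label in annotations.items():
                    if pos in positions:
                        labels.append((j, label))
                        used_positions.add(pos)
        rows.append(replace(row, conserved_columns=flagged, labels=tuple(labels)))

    if annotations and reference_index is not None:
        missed = set(annotations) - used_positions
        for pos in sorted(missed):
            warnings.warn(
                f"annotation position {pos} ({annotations[pos]}) maps to no flagged APC column",
                stacklevel=2,
            )
    return RankedTable(rows=tuple(rows))
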