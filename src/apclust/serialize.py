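"""JSON round-tripping of scored APC sets, used by the command line.

The on-disk form keeps everything needed to re-rank, re-render and
annotate without touching the original sequences: aligned rows, member
pattern strings with their occurrence lists, the four measures, the
per-column redundancies, and the checksum of the data space they were
scored against.
"""

from __future__ import annotations

import json
from pathlib import Path

from .apc_clustering import APC, AlignedPattern
from .errors import ValidationError
from .measures import ScoredAPC
from .pattern_discovery import Occurrence, Pattern


def scored_apcs_to_json(
    scored: list[ScoredAPC],
    alphabet_mode: str,
    base_size: int,
    pattern_count: int,
    sequence_checksum: str,
    sequence_ids: list[str],
) -> str:
    payload = {
        "alphabet": alphabet_mode,
        "base_size": base_size,
        "pattern_count": pattern_count,
        "sequence_checksum": sequence_checksum,
        "sequence_ids": sequence_ids,
        "apcs": [
            {
                "rows": list(sc.apc.rows),
                "members": [
                    {
                        "string": ap.source.string,
                        "score": ap.source.score,
                        "occurrences": [[o.seq_index, o.start] for o in ap.source.occurrences or ()],
                    }
                    for ap in sc.apc.members
                ],
                "coverage": sc.coverage,
                "occurrence_count": sc.occurrence_count,
                "quality": sc.quality,
                "expected": sc.expected,
                "standard_residual": sc.standard_residual,
                "column_redundancy": list(sc.column_redundancy),
            }
            for sc in scored
        ],
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def scored_apcs_from_json(text: str) -> tuple[list[ScoredAPC], dict]:
    """Rebuild ScoredAPC objects plus the run metadata dict."""
    payload = json.loads(text)
    scored = []
    for entry in payload["apcs"]:
        members = []
        for row, member in zip(entry["rows"], entry["members"]):
            occs = tuple(
                Occurrence(k, start, start + len(member["string"]) - 1)
                for k, start in member["occurrences"]
            )
            pattern = Pattern(string=member["string"], occurrences=occs, score=member["score"])
            members.append(AlignedPattern(source=pattern, row=row))
        if len(members) != len(entry["rows"]):
            raise ValidationError("rows and members lists disagree")
        scored.append(
            ScoredAPC(
                apc=APC(members=tuple(members)),
                coverage=entry["coverage"],
                occurrence_count=entry["occurrence_count"],
                quality=entry["quality"],
                expected=entry["expected"],
                standard_residual=entry["standard_residual"],
                column_redundancy=tuple(entry["column_redundancy"]),
                data_checksum=payload["sequence_checksum"],
            )
        )
    meta = {k: payload[k] for k in payload if k != "apcs"}
    return scored, meta


def write_scored_apcs(path: str | Path, *args, **kwargs) -> None:
    Path(path).write_text(scored_apcs_to_json(*args, **kwargs) + "\n")


def read_scored_apcs(path: str | Path) -> tuple[list[ScoredAPC], dict]:
    return scored_apcs_from_json(Path(path).read_text())
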