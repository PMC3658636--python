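"""Dereplication: collapse identical reads into representatives with counts.

Identity is exact full-length string equality (after case normalization at
ingest) — no clustering below 100% identity. Each representative is named
``<PRIMER>_<ordinal>_<count>``, e.g. ``ML_0001_946``: primer-set code,
zero-padded rank, and the number of reads it represents. The count travels
with the representative so every downstream tally can weight by it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .demux import DemuxedRead


@dataclass
class UniqueSequence:
    name: str
    primer_name: str
    sequence: str
    count: int
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.count != len(self.member_ids):
            raise ValueError(
                f"{self.name}: count {self.count} != members {len(self.member_ids)}"
            )
        if self.count < 1:
            raise ValueError(f"{self.name}: count must be positive")


def dereplicate(
    reads: Iterable[DemuxedRead | tuple[str, str]], primer_name: str
) -> list[UniqueSequence]:
    """Collapse identical sequences within one primer bin.

    Output is sorted by descending count, ties broken lexicographically by
    sequence (deterministic across runs); the sum of counts equals the number
    of input reads.
    """
    groups: dict[str, list[str]] = {}
    for r in reads:
        rid, seq = (r.read_id, r.sequence) if isinstance(r, DemuxedRead) else r
        groups.setdefault(seq.upper(), []).append(rid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        UniqueSequence(
            name=f"{primer_name}_{i:04d}_{len(ids)}",
            primer_name=primer_name,
            sequence=seq,
            count=len(ids),
            member_ids=ids,
        )
        for i, (seq, ids) in enumerate(ordered, start=1)
    ]


def write_unique_fasta(uniques: Sequence[UniqueSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for u in uniques:
            fh.write(f">{u.name}\n{u.sequence}\n")


def write_mapping(uniques: Sequence[UniqueSequence], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "count", "member_ids"])
        for u in uniques:
            w.writerow([u.name, u.count, ",".join(u.member_ids)])
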