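"""Hit filtering, top-hit taxonomic assignment, and count-weighted tallies.

The assignment rule is deliberately simple: after discarding short
alignments, weak E-values, sub-threshold identities and
uncultured/environmental subjects, each dereplicated query takes the species
of its single highest-scoring surviving hit. A query with no surviving hit is
reported as the unassigned class. Tallies weight every query by its
dereplication count, so the species totals are in units of reads, not of
unique sequences.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .derep import UniqueSequence
from .errors import ConfigError
from .reference import ReferenceRecord, UNASSIGNED_LABEL
from .search import SearchHit


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds applied to raw hits before top-hit selection.

    * ``min_alignment_bp`` — minimum alignment length, inclusive.
    * ``max_evalue`` — E-value cutoff, exclusive (a hit at exactly the
      threshold is removed).
    * ``min_percent_identity`` — inclusive; set to 0 to disable.
    * ``exclude_keywords`` — case-insensitive substrings that disqualify a
      subject by its description or species label (environmental clones).
    """

    min_alignment_bp: int = 50
    max_evalue: float = 1e-6
    min_percent_identity: float = 97.0
    exclude_keywords: tuple[str, ...] = ("uncultured",)

    def __post_init__(self) -> None:
        if self.min_alignment_bp <= 0 or self.max_evalue <= 0:
            raise ConfigError("filter thresholds must be positive")
        if self.min_percent_identity < 0 or self.min_percent_identity > 100:
            raise ConfigError("min_percent_identity must be in [0, 100]")


@dataclass
class AssignmentRecord:
    unique_name: str
    count: int
    assigned_species: str
    assigned_accession: str | None = None
    best_hit: SearchHit | None = None

    @property
    def is_assigned(self) -> bool:
        return self.assigned_species != UNASSIGNED_LABEL


def _excluded(hit: SearchHit, config: FilterConfig, rec: ReferenceRecord | None) -> bool:
    if not config.exclude_keywords:
        return False
    texts = [hit.subject_description]
    if rec is not None:
        texts.append(rec.species_label)
        if rec.uncultured:
            return True
    lowered = [t.lower() for t in texts]
    return any(kw.lower() in t for kw in config.exclude_keywords for t in lowered)


def filter_hits(
    hits: Iterable[SearchHit],
    config: FilterConfig = FilterConfig(),
    reference_annotations: Mapping[str, ReferenceRecord] | None = None,
) -> list[SearchHit]:
    """Keep hits passing all thresholds and not matching any exclude keyword.

    Alignment-length and identity thresholds are inclusive; the E-value
    threshold is strict (``evalue < max_evalue``). Subjects flagged uncultured
    in the annotations, or whose description contains an exclude keyword, are
    removed regardless of score.
    """
    ann = reference_annotations or {}
    out = []
    for h in hits:
        if h.aligned_length < config.min_alignment_bp:
            continue
        if not h.evalue < config.max_evalue:
            continue
        if h.percent_identity < config.min_percent_identity:
            continue
        if _excluded(h, config, ann.get(h.subject_accession)):
            continue
        out.append(h)
    return out


def assign_top_hit(
    unique_sequence: UniqueSequence,
    surviving_hits: Sequence[SearchHit],
    reference_annotations: Mapping[str, ReferenceRecord] | None = None,
) -> AssignmentRecord:
    """Assign the species of the highest-scoring surviving hit.

    Ties: lower E-value, then higher percent identity, then lexicographically
    smallest accession. An empty hit list yields the unassigned class.
    """
    if not surviving_hits:
        return AssignmentRecord(
            unique_name=unique_sequence.name,
            count=unique_sequence.count,
            assigned_species=UNASSIGNED_LABEL,
        )
    best = min(
        surviving_hits,
        key=lambda h: (-h.score, h.evalue, -h.percent_identity, h.subject_accession),
    )
    ann = (reference_annotations or {}).get(best.subject_accession)
    species = ann.species_label if ann is not None else best.subject_description
    return AssignmentRecord(
        unique_name=unique_sequence.name,
        count=unique_sequence.count,
        assigned_species=species,
        assigned_accession=best.subject_accession,
        best_hit=best,
    )


def assign_all(
    uniques: Sequence[UniqueSequence],
    hits_by_query: Mapping[str, Sequence[SearchHit]],
    config: FilterConfig = FilterConfig(),
    reference_annotations: Mapping[str, ReferenceRecord] | None = None,
) -> list[AssignmentRecord]:
    return [
        assign_top_hit(
            u,
            filter_hits(hits_by_query.get(u.name, ()), config, reference_annotations),
            reference_annotations,
        )
        for u in uniques
    ]


def tally(
    assignment_records: Iterable[AssignmentRecord],
) -> tuple[dict[str, int], int]:
    """Count-weighted species tally plus the unassigned read count.

    Each record contributes its dereplication count, so the totals are
    conserved: sum(tally) + unassigned == sum of all dereplication counts.
    """
    counts: dict[str, int] = {}
    unassigned = 0
    for rec in assignment_records:
        if rec.is_assigned:
            counts[rec.assigned_species] = counts.get(rec.assigned_species, 0) + rec.count
        else:
            unassigned += rec.count
    return counts, unassigned


def write_assignments(records: Sequence[AssignmentRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["unique_name", "count", "species", "accession",
             "score", "evalue", "pident", "aligned_length"]
        )
        for r in records:
            h = r.best_hit
            w.writerow(
                [
                    r.unique_name,
                    r.count,
                    r.assigned_species,
                    r.assigned_accession or "",
                    "" if h is None else f"{h.score:g}",
                    "" if h is None else f"{h.evalue:.3e}",
                    "" if h is None else f"{h.percent_identity:.2f}",
                    "" if h is None else h.aligned_length,
                ]
            )
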