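"""Annotated mcrA/mrtA reference database and the bundled hit-tally fixture.

The reference couples a FASTA of marker-gene sequences with a TSV annotation
table (taxonomy, methanogenesis-pathway codes, cultured/uncultured status).
Pathway codes follow the conventional shorthand used for methanogens:

* ``1`` — acetoclastic (acetate dismutated to CH4 + CO2)
* ``2`` — CO2 reduction with H2 (hydrogenotrophic)
* ``2*`` — CO2 reduction with H2 *and* formate as electron donors
* ``3`` — methylotrophic (disproportionation of methylated compounds)

``2*`` refines ``2``: every formate-capable organism is also hydrogenotrophic.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

from .errors import DataError
from .iupac import IUPAC_SETS

#: Label used for queries with no surviving database hit.
UNASSIGNED_LABEL = "No significant similarity found"

#: Species-label keywords that mark environmental/uncultured records.
DEFAULT_UNCULTURED_KEYWORDS = ("uncultured",)


@dataclass(frozen=True)
class MetabolismCode:
    """Methanogenesis-pathway capability flags for one organism."""

    acetoclastic: bool = False
    co2_reduction: bool = False
    formate_capable: bool = False
    methylotrophic: bool = False

    def __post_init__(self) -> None:
        if self.formate_capable and not self.co2_reduction:
            raise ValueError("formate_capable implies co2_reduction ('2*' refines '2')")
        if not any(
            (self.acetoclastic, self.co2_reduction, self.methylotrophic)
        ):
            raise ValueError("a metabolism annotation must set at least one pathway")

    @classmethod
    def from_string(cls, text: str) -> "MetabolismCode | None":
        """Parse a pathway-code string like ``"1, 2, 3"``, ``"2*"`` or ``"NA"``.

        Returns None for NA/empty (no annotation). ``2*`` is one token: it sets
        both co2_reduction and formate_capable.
        """
        t = text.strip()
        if t in ("", "NA", "na", "-", "None"):
            return None
        flags = dict.fromkeys(
            ("acetoclastic", "co2_reduction", "formate_capable", "methylotrophic"),
            False,
        )
        for tok in (p.strip() for p in t.split(",")):
            if tok == "1":
                flags["acetoclastic"] = True
            elif tok == "2":
                flags["co2_reduction"] = True
            elif tok in ("2*", "2∗", "2^*"):
                flags["co2_reduction"] = True
                flags["formate_capable"] = True
            elif tok == "3":
                flags["methylotrophic"] = True
            else:
                raise ValueError(f"unparseable metabolism token {tok!r} in {text!r}")
        return cls(**flags)

    def to_string(self) -> str:
        parts = []
        if self.acetoclastic:
            parts.append("1")
        if self.co2_reduction:
            parts.append("2*" if self.formate_capable else "2")
        if self.methylotrophic:
            parts.append("3")
        return ", ".join(parts)


def derive_genus(species_label: str) -> str:
    """Genus = first whitespace token of the full organism string."""
    return species_label.split()[0] if species_label.strip() else ""


@dataclass
class ReferenceRecord:
    """One annotated reference sequence (or tally-only annotation row)."""

    accession: str
    species_label: str
    order: str
    genus: str = ""
    gene: str = "mcrA"
    metabolism: MetabolismCode | None = None
    uncultured: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.gene not in ("mcrA", "mrtA"):
            raise ValueError(f"gene must be mcrA or mrtA, got {self.gene!r}")
        if not self.genus:
            self.genus = derive_genus(self.species_label)
        if self.uncultured and self.metabolism is not None:
            raise ValueError(
                f"{self.accession}: uncultured records carry no metabolism annotation"
            )
        if self.sequence is not None:
            bad = set(self.sequence.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(
                    f"{self.accession}: non-IUPAC characters in sequence: {sorted(bad)!r}"
                )


class ReferenceDatabase:
    """Reference records indexed by accession; tracks total residue count.

    The total residue count is the search-space size *n* used by the
    Karlin-Altschul E-value computation downstream.
    """

    def __init__(self, records: Iterable[ReferenceRecord]):
        self._records: dict[str, ReferenceRecord] = {}
        for rec in records:
            if rec.accession in self._records:
                raise DataError(f"duplicate accession {rec.accession!r}")
            self._records[rec.accession] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self._records.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __getitem__(self, accession: str) -> ReferenceRecord:
        return self._records[accession]

    @property
    def total_residues(self) -> int:
        return sum(len(r.sequence) for r in self if r.sequence is not None)

    def species_annotations(self) -> dict[str, ReferenceRecord]:
        """Map species label -> one representative record (taxonomy/metabolism)."""
        out: dict[str, ReferenceRecord] = {}
        for rec in self:
            out.setdefault(rec.species_label, rec)
        return out

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self:
                if rec.sequence is None:
                    continue
                fh.write(f">{rec.accession} {rec.species_label}\n{rec.sequence}\n")

    def write_annotation(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["accession", "species", "genus", "order", "gene", "metabolism", "uncultured"]
            )
            for rec in self:
                w.writerow(
                    [
                        rec.accession,
                        rec.species_label,
                        rec.genus,
                        rec.order,
                        rec.gene,
                        "NA" if rec.metabolism is None else rec.metabolism.to_string(),
                        "true" if rec.uncultured else "false",
                    ]
                )


def _read_annotation_rows(annotation_path: str | Path) -> dict[str, dict[str, str]]:
    rows: dict[str, dict[str, str]] = {}
    with open(annotation_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"accession", "species", "order"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise DataError(
                f"{annotation_path}: annotation TSV needs at least columns "
                f"{sorted(required)}; got {reader.fieldnames}"
            )
        for row in reader:
            acc = row["accession"].strip()
            if acc in rows:
                raise DataError(f"{annotation_path}: duplicate accession {acc!r}")
            rows[acc] = row
    return rows


def load_reference(fasta_path: str | Path, annotation_path: str | Path) -> ReferenceDatabase:
    """Load a FASTA + annotation TSV into a :class:`ReferenceDatabase`.

    Every FASTA record must have a matching annotation row (keyed on the first
    whitespace token of the FASTA header); a missing row is a hard error naming
    the accession.
    """
    ann = _read_annotation_rows(annotation_path)
    records = []
    seen = set()
    for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
        acc = seqrec.id
        if acc in seen:
            raise DataError(f"{fasta_path}: duplicate accession {acc!r}")
        seen.add(acc)
        if acc not in ann:
            raise DataError(f"no annotation row for accession {acc!r}")
        row = ann[acc]
        try:
            metabolism = MetabolismCode.from_string(row.get("metabolism", "NA"))
        except ValueError as exc:
            raise DataError(f"accession {acc!r}: {exc}") from exc
        uncult_raw = (row.get("uncultured") or "").strip().lower()
        species = row["species"].strip()
        if uncult_raw in ("true", "1", "yes"):
            uncultured = True
        elif uncult_raw in ("false", "0", "no"):
            uncultured = False
        else:
            uncultured = any(
                kw in species.lower() for kw in DEFAULT_UNCULTURED_KEYWORDS
            )
        records.append(
            ReferenceRecord(
                accession=acc,
                species_label=species,
                genus=(row.get("genus") or "").strip(),
                order=row["order"].strip(),
                gene=(row.get("gene") or "mcrA").strip() or "mcrA",
                metabolism=metabolism,
                uncultured=uncultured,
                sequence=str(seqrec.seq).upper(),
            )
        )
    return ReferenceDatabase(records)


@dataclass(frozen=True)
class TallyRow:
    species_label: str
    order: str
    metabolism: MetabolismCode | None
    hits: int
    accession: str = ""

    @property
    def genus(self) -> str:
        return derive_genus(self.species_label)


@dataclass
class TallyFixture:
    """A printed species-by-hit-count table with taxonomy and pathway codes.

    Exactly one row carries the unassigned class (:data:`UNASSIGNED_LABEL`)
    with NA metabolism; its count is the number of query reads that found no
    significant database match.
    """

    rows: list[TallyRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        na_rows = [r for r in self.rows if r.species_label == UNASSIGNED_LABEL]
        if len(na_rows) != 1:
            raise DataError(
                f"expected exactly one {UNASSIGNED_LABEL!r} row, found {len(na_rows)}"
            )
        if na_rows[0].metabolism is not None:
            raise DataError("the unassigned row must have NA metabolism")
        if any(r.hits < 1 for r in self.rows):
            raise DataError("all hit counts must be >= 1")

    @property
    def unassigned(self) -> int:
        return next(r.hits for r in self.rows if r.species_label == UNASSIGNED_LABEL)

    @property
    def assigned_total(self) -> int:
        return sum(r.hits for r in self.rows if r.species_label != UNASSIGNED_LABEL)

    @property
    def total_hits(self) -> int:
        return sum(r.hits for r in self.rows)

    def species_tally(self) -> dict[str, int]:
        """Species label -> hit count, excluding the unassigned row."""
        return {
            r.species_label: r.hits
            for r in self.rows
            if r.species_label != UNASSIGNED_LABEL
        }

    def annotations(self) -> dict[str, TallyRow]:
        """Species label -> row (taxonomy + metabolism), excluding unassigned."""
        return {
            r.species_label: r
            for r in self.rows
            if r.species_label != UNASSIGNED_LABEL
        }


def load_tally_fixture(path: str | Path | None = None) -> TallyFixture:
    """Load a tally TSV (columns: species, accession, order, metabolism, hits).

    With no path, loads the bundled anaerobic-digester mcrA tally shipped
    with the package.
    """
    if path is None:
        resource = importlib.resources.files("mcraprof").joinpath(
            "data/digester_mcra_tally.tsv"
        )
        with importlib.resources.as_file(resource) as p:
            return load_tally_fixture(p)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"species", "order", "metabolism", "hits"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise DataError(
                f"{path}: tally TSV needs columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                metabolism = MetabolismCode.from_string(row["metabolism"])
                hits = int(row["hits"])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            rows.append(
                TallyRow(
                    species_label=row["species"].strip(),
                    order=row["order"].strip(),
                    metabolism=metabolism,
                    hits=hits,
                    accession=(row.get("accession") or "").strip(),
                )
            )
    return TallyFixture(rows=rows)


def write_tally(
    tally: Mapping[str, int],
    unassigned: int,
    annotations: Mapping[str, "TallyRow | ReferenceRecord"],
    path: str | Path,
) -> None:
    """Write a species tally in the fixture's TSV layout (descending hits)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species", "accession", "order", "metabolism", "hits"])
        items = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        if unassigned > 0:
            # Insert the unassigned row in count order, like the printed table.
            items.append((UNASSIGNED_LABEL, unassigned))
            items.sort(key=lambda kv: (-kv[1], kv[0]))
        for species, hits in items:
            if species == UNASSIGNED_LABEL:
                w.writerow([species, "", "NA", "NA", hits])
                continue
            ann = annotations[species]
            met = ann.metabolism
            w.writerow(
                [
                    species,
                    getattr(ann, "accession", ""),
                    ann.order,
                    "NA" if met is None else met.to_string(),
                    hits,
                ]
            )
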