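"""Demultiplexing of pooled pyrosequencing reads by MID tag, plus length filtering.

Pooled 454-style runs prepend a short multiplex-identifier (MID) barcode to
each amplicon so that reads from different primer sets can share a plate
region. This stage sorts reads into per-primer bins by tag prefix, strips the
tag, and discards short reads (primer-dimer artifacts) below a length cutoff.
"""

from __future__ import annotations

import csv
import json
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ConfigError, DataError
from .iupac import IUPAC_SETS, iupac_match, normalize, revcomp

#: Reads at or below this length are treated as primer-dimer artifacts.
DEFAULT_MIN_LENGTH_EXCLUSIVE = 100


@dataclass
class PrimerSet:
    """A named degenerate primer pair with its MID tag and expected amplicon size."""

    name: str
    forward: str
    reverse: str
    mid_tag: str = ""
    expected_amplicon_bp: int = 0

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ConfigError(f"primer set {self.name!r}: empty {label} primer")
            bad = set(seq.upper()) - set(IUPAC_SETS)
            if bad:
                raise ConfigError(
                    f"primer set {self.name!r}: non-IUPAC characters in {label} "
                    f"primer: {sorted(bad)!r}"
                )
        if self.expected_amplicon_bp <= 0:
            raise ConfigError(
                f"primer set {self.name!r}: expected_amplicon_bp must be positive"
            )
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        self.mid_tag = self.mid_tag.upper()


@dataclass
class DemuxedRead:
    read_id: str
    primer_name: str
    sequence: str
    original_length: int


def load_primer_sets(path: str | Path | None = None) -> list[PrimerSet]:
    """Load primer sets from TSV or JSON (columns/keys: name, forward, reverse,
    mid_tag, expected_amplicon_bp). With no path, loads the bundled mcrA sets
    ML/MCR/ME (without MID tags — tags are run-specific)."""
    if path is None:
        resource = importlib.resources.files("mcraprof").joinpath(
            "data/mcra_primers.tsv"
        )
        with importlib.resources.as_file(resource) as p:
            return load_primer_sets(p)
    path = Path(path)
    rows: list[dict]
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    sets = []
    for row in rows:
        try:
            sets.append(
                PrimerSet(
                    name=row["name"],
                    forward=row["forward"],
                    reverse=row["reverse"],
                    mid_tag=(row.get("mid_tag") or ""),
                    expected_amplicon_bp=int(row["expected_amplicon_bp"]),
                )
            )
        except KeyError as exc:
            raise DataError(f"{path}: primer table missing field {exc}") from exc
    return sets


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA/.fna file into (id, sequence) pairs, normalized to
    uppercase DNA (U mapped to T)."""
    return [(rec.id, normalize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def _mismatches(pattern: str, window: str, budget: int) -> int | None:
    """Mismatch count of IUPAC pattern vs concrete window, or None if > budget."""
    mm = 0
    for p, b in zip(pattern, window):
        if b not in IUPAC_SETS[p]:
            mm += 1
            if mm > budget:
                return None
    return mm


def find_primer(
    sequence: str, primer: str, max_mismatches: int = 0
) -> tuple[int, str] | None:
    """Locate a degenerate primer in a read.

    Scans the forward strand left to right first, then the reverse complement
    of the read, returning the leftmost position (0-based, in the scanned
    strand's coordinates) with at most ``max_mismatches`` IUPAC-incompatible
    positions, as ``(position, '+')`` or ``(position, '-')``; None if absent.
    """
    if max_mismatches < 0:
        raise ConfigError("max_mismatches must be >= 0")
    seq = normalize(sequence)
    pat = normalize(primer)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(len(s) - len(pat) + 1):
            if _mismatches(pat, s[i : i + len(pat)], max_mismatches) is not None:
                return (i, strand)
    return None


def demultiplex(
    reads: Iterable[tuple[str, str]],
    primer_sets: Sequence[PrimerSet],
    max_tag_mismatches: int = 0,
) -> tuple[dict[str, list[DemuxedRead]], list[tuple[str, str]]]:
    """Sort reads into per-primer bins by MID-tag prefix; strip the tag.

    Every input read lands in exactly one bin or in the reject list
    (multiset conservation). A read whose prefix matches the tags of two
    primer sets equally well under a nonzero mismatch budget is ambiguous and
    rejected. Matching is case-insensitive (reads are normalized on ingest).
    """
    tags = [ps.mid_tag for ps in primer_sets]
    if any(not t for t in tags):
        raise ConfigError("every primer set needs a non-empty MID tag to demultiplex")
    if len(set(tags)) != len(tags):
        raise ConfigError("primer sets have duplicate MID tags")

    bins: dict[str, list[DemuxedRead]] = {ps.name: [] for ps in primer_sets}
    rejects: list[tuple[str, str]] = []
    for rid, raw in reads:
        seq = normalize(raw)
        best: tuple[int, PrimerSet] | None = None
        ambiguous = False
        for ps in primer_sets:
            if len(seq) < len(ps.mid_tag):
                continue
            mm = _mismatches(ps.mid_tag, seq[: len(ps.mid_tag)], max_tag_mismatches)
            if mm is None:
                continue
            if best is None or mm < best[0]:
                best, ambiguous = (mm, ps), False
            elif mm == best[0]:
                ambiguous = True
        if best is None or ambiguous:
            rejects.append((rid, seq))
            continue
        ps = best[1]
        bins[ps.name].append(
            DemuxedRead(
                read_id=rid,
                primer_name=ps.name,
                sequence=seq[len(ps.mid_tag) :],
                original_length=len(seq),
            )
        )
    return bins, rejects


def length_filter(
    reads: Sequence[DemuxedRead], min_exclusive: int = DEFAULT_MIN_LENGTH_EXCLUSIVE
) -> tuple[list[DemuxedRead], list[DemuxedRead]]:
    """Partition reads into (kept, discarded) by strict length cutoff.

    A read is kept iff ``len(sequence) > min_exclusive``; the boundary length
    itself is discarded. Sub-cutoff reads are overwhelmingly primer dimers.
    """
    kept = [r for r in reads if len(r.sequence) > min_exclusive]
    discarded = [r for r in reads if len(r.sequence) <= min_exclusive]
    return kept, discarded


def write_demux_report(
    bins: dict[str, list[DemuxedRead]],
    rejects: Sequence[tuple[str, str]],
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["bin", "reads"])
        for name, rs in bins.items():
            w.writerow([name, len(rs)])
        w.writerow(["rejected", len(rejects)])
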