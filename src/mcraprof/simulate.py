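"""Synthetic tagged-amplicon reads from a mock reference community.

The generator emulates a pooled pyrosequencing run over a known community so
that every downstream stage (demultiplexing, length filtering,
dereplication, search, assignment, profiling) can be tested against an exact
per-read truth table without any external data:

* mock reference templates carry in-silico PCR sites for each primer set at
  the primer set's expected amplicon geometry;
* each read is ``MID tag + amplicon``, its template drawn from configurable
  relative abundances;
* a configurable fraction of reads are short primer-dimer junk (tag plus a
  random sub-100 bp sequence), mirroring the artifact class that motivates
  the length filter;
* sequencing noise is i.i.d. per-base substitution (optionally indels, for
  stress tests of the aligner) applied downstream of the tag.

Degenerate primer positions in an amplicon are resolved from the template
site by default, so an error-free run from k templates dereplicates to
exactly k unique sequences per primer; ``resolve='random'`` draws each
degenerate position uniformly from its allowed bases instead, modelling a
heterogeneous primer pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .demux import PrimerSet, find_primer
from .errors import ConfigError, DataError
from .iupac import IUPAC_SETS, revcomp
from .reference import MetabolismCode, ReferenceDatabase, ReferenceRecord

_BASES = np.array(list("ACGT"))
_ORDER_CYCLE = ("Methanosarcinales", "Methanobacteriales", "Methanomicrobiales")
_METABOLISM_CYCLE = ("1", "2", "2*", "1, 2, 3")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic run; defaults give a clean, noise-free pool."""

    seed: int = 0
    n_reads_per_primer: dict[str, int] = field(default_factory=dict)
    abundances: dict[str, float] = field(default_factory=dict)
    error_rate: float = 0.0
    dimer_fraction: float = 0.0
    tag_length: int = 10
    indel_rate: float = 0.0
    revcomp_fraction: float = 0.0
    tag_error: bool = False
    resolve: str = "template"

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1 or not 0 <= self.indel_rate < 1:
            raise ConfigError("error rates must be in [0, 1)")
        if not 0 <= self.dimer_fraction < 1:
            raise ConfigError("dimer_fraction must be in [0, 1)")
        if self.abundances and (
            min(self.abundances.values()) < 0 or max(self.abundances.values()) <= 0
        ):
            raise ConfigError("abundances must be nonnegative with at least one positive")
        if self.resolve not in ("template", "random"):
            raise ConfigError("resolve must be 'template' or 'random'")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_tags(
    rng: np.random.Generator,
    n: int,
    length: int = 10,
    min_hamming: int = 3,
    max_tries: int = 10_000,
) -> list[str]:
    """Random fixed-length MID barcodes with pairwise Hamming distance >= 3,
    so single-base tag errors cannot cross-assign reads."""
    tags: list[str] = []
    for _ in range(max_tries):
        cand = random_dna(rng, length)
        if all(
            sum(a != b for a, b in zip(cand, t)) >= min_hamming for t in tags
        ):
            tags.append(cand)
            if len(tags) == n:
                return tags
    raise ConfigError(f"could not generate {n} tags of length {length}")


def assign_tags(
    primer_sets: Sequence[PrimerSet], rng: np.random.Generator, tag_length: int = 10
) -> list[PrimerSet]:
    """Return copies of the primer sets with generated MID tags where missing."""
    tags = generate_tags(rng, len(primer_sets), tag_length)
    out = []
    for ps, tag in zip(primer_sets, tags):
        out.append(
            PrimerSet(
                name=ps.name,
                forward=ps.forward,
                reverse=ps.reverse,
                mid_tag=ps.mid_tag or tag,
                expected_amplicon_bp=ps.expected_amplicon_bp,
            )
        )
    return out


def _resolve_site(pattern: str, rng: np.random.Generator) -> str:
    """One concrete realization of a degenerate pattern (uniform per position)."""
    return "".join(
        b if len(IUPAC_SETS[b]) == 1 else rng.choice(sorted(IUPAC_SETS[b]))
        for b in pattern
    )


def build_mock_community(
    primer_sets: Sequence[PrimerSet],
    n_templates: int,
    rng: np.random.Generator,
    spacer: int = 40,
) -> ReferenceDatabase:
    """Mock annotated references, each carrying one amplicon block per primer set.

    Within a template, the block for primer set P is a concrete forward-primer
    site, random filler, and the reverse complement of a concrete
    reverse-primer site, sized so the in-silico amplicon is exactly
    ``P.expected_amplicon_bp``. Fillers are independent random DNA, so
    templates share only the short primer sites.
    """
    records = []
    for i in range(n_templates):
        parts = [random_dna(rng, spacer)]
        for ps in primer_sets:
            insert_len = ps.expected_amplicon_bp - len(ps.forward) - len(ps.reverse)
            if insert_len < 0:
                raise ConfigError(
                    f"primer set {ps.name!r}: expected amplicon shorter than primers"
                )
            parts.append(_resolve_site(ps.forward, rng))
            parts.append(random_dna(rng, insert_len))
            parts.append(revcomp(_resolve_site(ps.reverse, rng)))
            parts.append(random_dna(rng, spacer))
        order = _ORDER_CYCLE[i % len(_ORDER_CYCLE)]
        genus = f"Mockgenus{i + 1}"
        records.append(
            ReferenceRecord(
                accession=f"MOCK{i + 1:04d}.1",
                species_label=f"{genus} synthetica strain {i + 1}",
                order=order,
                gene="mcrA",
                metabolism=MetabolismCode.from_string(
                    _METABOLISM_CYCLE[i % len(_METABOLISM_CYCLE)]
                ),
                uncultured=False,
                sequence="".join(parts),
            )
        )
    return ReferenceDatabase(records)


def simulate_amplicon(
    reference_seq: str,
    primer_set: PrimerSet,
    rng: np.random.Generator,
    resolve: str = "template",
) -> str:
    """In-silico PCR product: ``tag + forward primer + insert + revcomp(reverse)``.

    The template must contain a forward-primer site and, downstream of it,
    the reverse complement of a reverse-primer site (IUPAC matching). With
    ``resolve='template'`` degenerate primer positions copy the template base
    (the amplicon is then an exact substring of the template, tag aside);
    with ``resolve='random'`` each degenerate position is drawn uniformly
    from its allowed bases.
    """
    fwd = find_primer(reference_seq, primer_set.forward, 0)
    if fwd is None or fwd[1] != "+":
        raise DataError(
            f"no forward-primer site for primer set {primer_set.name!r} in template"
        )
    fstart = fwd[0]
    tail = reference_seq[fstart + len(primer_set.forward) :]
    rev_site_pattern = revcomp(primer_set.reverse)
    rev = find_primer(tail, rev_site_pattern, 0)
    if rev is None or rev[1] != "+":
        raise DataError(
            f"no reverse-primer site for primer set {primer_set.name!r} in template"
        )
    rstart = fstart + len(primer_set.forward) + rev[0]
    insert = reference_seq[fstart + len(primer_set.forward) : rstart]

    if resolve == "template":
        fwd_seq = reference_seq[fstart : fstart + len(primer_set.forward)]
        rev_rc = reference_seq[rstart : rstart + len(primer_set.reverse)]
    elif resolve == "random":
        fwd_seq = _resolve_site(primer_set.forward, rng)
        rev_rc = revcomp(_resolve_site(primer_set.reverse, rng))
    else:
        raise ConfigError("resolve must be 'template' or 'random'")
    return primer_set.mid_tag + fwd_seq + insert + rev_rc


def _mutate(seq: str, rate: float, indel_rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Apply i.i.d. substitutions (and optional indels); returns (seq, n_errors)."""
    if rate == 0 and indel_rate == 0:
        return seq, 0
    out = []
    n_err = 0
    for b in seq:
        if indel_rate and rng.random() < indel_rate:
            n_err += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(str(rng.choice(_BASES)))  # insertion before the base
        if rate and rng.random() < rate:
            n_err += 1
            b = str(rng.choice([x for x in "ACGT" if x != b]))
        out.append(b)
    return "".join(out), n_err


def generate_reads(
    db: ReferenceDatabase,
    primers: Sequence[PrimerSet],
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit the configured pooled read set plus its per-read truth table.

    Per primer set: ``round(n * dimer_fraction)`` reads are tagged junk of
    total length uniform in [20, 100); the rest are amplicons from templates
    drawn with probability proportional to ``config.abundances``.
    Deterministic for a fixed config (single seeded generator).
    """
    rng = np.random.default_rng(config.seed)
    for acc in config.abundances:
        if acc not in db:
            raise DataError(f"unknown accession in abundances: {acc!r}")
    accs = sorted(config.abundances)
    weights = np.array([config.abundances[a] for a in accs], dtype=float)
    probs = weights / weights.sum() if accs else None

    reads: list[tuple[str, str]] = []
    truth_rows = []
    for ps in primers:
        n = config.n_reads_per_primer.get(ps.name, 0)
        if n and not ps.mid_tag:
            raise ConfigError(f"primer set {ps.name!r} has no MID tag; run assign_tags")
        n_dimer = round(n * config.dimer_fraction)
        for i in range(n):
            rid = f"{ps.name}_read{i + 1:06d}"
            if i < n_dimer:
                total_len = int(rng.integers(20, 100))
                body_len = max(total_len - len(ps.mid_tag), 1)
                seq = ps.mid_tag + random_dna(rng, body_len)
                reads.append((rid, seq))
                truth_rows.append(
                    dict(read_id=rid, primer_name=ps.name, source_accession="",
                         is_dimer=True, n_errors=0)
                )
                continue
            if probs is None:
                raise ConfigError("abundances required for non-dimer reads")
            acc = accs[int(rng.choice(len(accs), p=probs))]
            template = db[acc].sequence
            assert template is not None
            amplicon = simulate_amplicon(template, ps, rng, resolve=config.resolve)
            tag, body = amplicon[: len(ps.mid_tag)], amplicon[len(ps.mid_tag) :]
            body, n_err = _mutate(body, config.error_rate, config.indel_rate, rng)
            if config.tag_error:
                tag, tag_err = _mutate(tag, config.error_rate, 0.0, rng)
                n_err += tag_err
            seq = tag + body
            if config.revcomp_fraction and rng.random() < config.revcomp_fraction:
                seq = revcomp(seq)
            reads.append((rid, seq))
            truth_rows.append(
                dict(read_id=rid, primer_name=ps.name, source_accession=acc,
                     is_dimer=False, n_errors=n_err)
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "primer_name", "source_accession", "is_dimer", "n_errors"],
    )
    return reads, truth
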