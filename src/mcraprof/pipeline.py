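"""End-to-end orchestration: demux -> length filter -> dereplicate -> search ->
assign -> community profile, with a conservation-audited run report.

The report re-asserts the pipeline's accounting identities on every run:
every input read ends up in exactly one demultiplexed bin or the reject
pile, dereplication counts sum to the number of length-passing reads, and
the assigned + unassigned totals reproduce that same sum. A run that breaks
any identity aborts rather than reporting silently inconsistent numbers.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from . import assign as assign_mod
from . import demux as demux_mod
from . import derep as derep_mod
from . import profile as profile_mod
from . import search as search_mod
from .errors import ConfigError, DataError
from .reference import (
    ReferenceDatabase,
    load_reference,
    load_tally_fixture,
    write_tally,
)

MODES = ("internal_search", "external_blast_tabular", "profile_only")


@dataclass
class RunConfig:
    """Paths, thresholds, and mode for one reproducible pipeline run."""

    outdir: Path
    reads: Path | None = None
    primers: Path | None = None
    reference_fasta: Path | None = None
    annotation: Path | None = None
    hits: Path | None = None
    tally: Path | None = None
    mode: str = "internal_search"
    min_len: int = demux_mod.DEFAULT_MIN_LENGTH_EXCLUSIVE
    max_tag_mismatches: int = 0
    min_alignment_bp: int = 50
    max_evalue: float = 1e-6
    min_percent_identity: float = 97.0
    exclude_keywords: tuple[str, ...] = ("uncultured",)
    ka_k: float = search_mod.DEFAULT_K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("reads", "primers", "reference_fasta", "annotation", "hits", "tally"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise ConfigError(f"{name} path does not exist: {p}")
        self.outdir = Path(self.outdir)

    def filter_config(self) -> assign_mod.FilterConfig:
        return assign_mod.FilterConfig(
            min_alignment_bp=self.min_alignment_bp,
            max_evalue=self.max_evalue,
            min_percent_identity=self.min_percent_identity,
            exclude_keywords=tuple(self.exclude_keywords),
        )


@dataclass
class RunReport:
    reads_in: int = 0
    reads_per_bin: dict[str, int] = field(default_factory=dict)
    reads_rejected: int = 0
    reads_length_filtered: int = 0
    unique_sequences: int = 0
    assigned: int = 0
    unassigned: int = 0
    stage_seconds: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def check_conservation(self) -> None:
        binned = sum(self.reads_per_bin.values())
        if self.reads_in != binned + self.reads_rejected:
            raise DataError(
                f"demux lost reads: {self.reads_in} in, "
                f"{binned} binned + {self.reads_rejected} rejected"
            )
        passing = binned - self.reads_length_filtered
        if self.assigned + self.unassigned != passing:
            raise DataError(
                f"tally lost reads: {self.assigned} assigned + "
                f"{self.unassigned} unassigned != {passing} length-passing"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _log(msg: str) -> None:
    print(f"[mcraprof] {msg}", file=sys.stderr)


def run_stages(
    reads: Sequence[tuple[str, str]],
    primer_sets: Sequence[demux_mod.PrimerSet],
    db: ReferenceDatabase,
    filter_config: assign_mod.FilterConfig | None = None,
    min_len: int = demux_mod.DEFAULT_MIN_LENGTH_EXCLUSIVE,
    max_tag_mismatches: int = 0,
    scheme: search_mod.ScoringScheme = search_mod.ScoringScheme(),
    ka_k: float = search_mod.DEFAULT_K,
    hits_by_query: Mapping[str, Sequence[search_mod.SearchHit]] | None = None,
) -> tuple[profile_mod.CommunityProfile, RunReport, dict]:
    """In-memory pipeline core; pass ``hits_by_query`` to skip the internal search.

    Returns the community profile, the audited run report, and a dict of
    intermediates (bins, uniques, assignments, tallies) for callers that
    write files or test stage wiring.
    """
    filter_config = filter_config or assign_mod.FilterConfig()
    report = RunReport(reads_in=len(reads))
    t0 = time.perf_counter()
    bins, rejects = demux_mod.demultiplex(reads, primer_sets, max_tag_mismatches)
    report.reads_per_bin = {name: len(rs) for name, rs in bins.items()}
    report.reads_rejected = len(rejects)
    report.stage_seconds["demux"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    kept_bins: dict[str, list[demux_mod.DemuxedRead]] = {}
    n_short = 0
    for name, rs in bins.items():
        kept, discarded = demux_mod.length_filter(rs, min_len)
        kept_bins[name] = kept
        n_short += len(discarded)
    report.reads_length_filtered = n_short
    report.stage_seconds["length_filter"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    uniques_by_bin = {
        name: derep_mod.dereplicate(rs, name) for name, rs in kept_bins.items()
    }
    all_uniques = [u for us in uniques_by_bin.values() for u in us]
    report.unique_sequences = len(all_uniques)
    report.stage_seconds["dereplicate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if hits_by_query is None:
        hits_by_query = search_mod.search_database(
            [(u.name, u.sequence) for u in all_uniques], db, scheme, ka_k
        )
    report.stage_seconds["search"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    annotations = {rec.accession: rec for rec in db}
    per_primer_tally: dict[str, dict[str, int]] = {}
    unassigned_per_primer: dict[str, int] = {}
    assignments: dict[str, list[assign_mod.AssignmentRecord]] = {}
    for name, us in uniques_by_bin.items():
        records = assign_mod.assign_all(us, hits_by_query, filter_config, annotations)
        assignments[name] = records
        t, ua = assign_mod.tally(records)
        per_primer_tally[name] = t
        unassigned_per_primer[name] = ua
    report.assigned = sum(sum(t.values()) for t in per_primer_tally.values())
    report.unassigned = sum(unassigned_per_primer.values())
    report.stage_seconds["assign"] = time.perf_counter() - t0

    species_ann = db.species_annotations()
    profile = profile_mod.CommunityProfile.build(
        per_primer_tally, unassigned_per_primer, species_ann
    )
    report.check_conservation()
    intermediates = dict(
        bins=bins,
        rejects=rejects,
        kept_bins=kept_bins,
        uniques_by_bin=uniques_by_bin,
        hits_by_query=hits_by_query,
        assignments=assignments,
        species_annotations=species_ann,
    )
    return profile, report, intermediates


def run_profile_only(tally_path: Path | None, outdir: Path) -> dict:
    """Profile a precomputed species tally (fixture layout) without search.

    Writes order/genus rollups and the pathway breakdown; returns the summary
    dict that is also written as JSON.
    """
    fixture = load_tally_fixture(tally_path)
    tally = fixture.species_tally()
    ann = fixture.annotations()
    orders = profile_mod.rollup(tally, ann, "order")
    genera = profile_mod.rollup(tally, ann, "genus")
    breakdown = profile_mod.pathway_breakdown(tally, ann, fixture.unassigned)
    summary = {
        "assigned_total": fixture.assigned_total,
        "unassigned": fixture.unassigned,
        "unassigned_pct_of_all": profile_mod.unassigned_fraction(tally, fixture.unassigned),
        "order_breakdown": {t: {"hits": n, "pct": 100 * f} for t, (n, f) in orders.items()},
        "genus_breakdown": {t: {"hits": n, "pct": 100 * f} for t, (n, f) in genera.items()},
        "pathways": asdict(breakdown),
    }
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "profile_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def run_pipeline(config: RunConfig) -> tuple[profile_mod.CommunityProfile | None, RunReport | dict]:
    """File-level entry point: load inputs per ``config.mode``, run the stages,
    and write all intermediates and the report under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.mode == "profile_only":
        _log("profile-only mode")
        summary = run_profile_only(config.tally, outdir)
        return None, summary

    if config.reads is None or config.primers is None:
        raise ConfigError("reads and primers paths are required in this mode")
    reads = demux_mod.read_fasta(config.reads)
    primer_sets = demux_mod.load_primer_sets(config.primers)
    _log(f"loaded {len(reads)} reads, {len(primer_sets)} primer sets")

    if config.reference_fasta is None or config.annotation is None:
        raise ConfigError("reference_fasta and annotation are required in this mode")
    db = load_reference(config.reference_fasta, config.annotation)
    _log(f"reference: {len(db)} records, {db.total_residues} residues")

    hits_by_query = None
    if config.mode == "external_blast_tabular":
        if config.hits is None:
            raise ConfigError("hits path required in external_blast_tabular mode")
        parsed = search_mod.parse_blast_tabular(config.hits)
        hits_by_query = {}
        for h in parsed:
            hits_by_query.setdefault(h.alignment.query_name, []).append(h)
        _log(f"parsed {len(parsed)} external hits")

    profile, report, inter = run_stages(
        reads,
        primer_sets,
        db,
        filter_config=config.filter_config(),
        min_len=config.min_len,
        max_tag_mismatches=config.max_tag_mismatches,
        ka_k=config.ka_k,
        hits_by_query=hits_by_query,
    )
    report.config = {
        k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(config).items()
    }

    for name, rs in inter["bins"].items():
        demux_mod.write_fasta(((r.read_id, r.sequence) for r in rs), outdir / f"bin_{name}.fasta")
    demux_mod.write_fasta(inter["rejects"], outdir / "rejected.fasta")
    demux_mod.write_demux_report(inter["bins"], inter["rejects"], outdir / "demux_report.tsv")
    for name, us in inter["uniques_by_bin"].items():
        derep_mod.write_unique_fasta(us, outdir / f"unique_{name}.fasta")
        derep_mod.write_mapping(us, outdir / f"unique_{name}.tsv")
    all_hits = [h for hs in inter["hits_by_query"].values() for h in hs]
    search_mod.write_hits(all_hits, outdir / "hits.tsv")
    for name, records in inter["assignments"].items():
        assign_mod.write_assignments(records, outdir / f"assignments_{name}.tsv")
    write_tally(
        profile.pooled, profile.unassigned, inter["species_annotations"],
        outdir / "tally_pooled.tsv",
    )
    profile.to_json(outdir / "profile.json")
    if profile.pooled:
        breakdown = profile_mod.pathway_breakdown(
            profile.pooled, inter["species_annotations"], profile.unassigned
        )
        (outdir / "pathways.json").write_text(
            json.dumps(asdict(breakdown), indent=2, sort_keys=True) + "\n"
        )
    report.to_json(outdir / "run_report.json")
    _log(
        f"done: {report.assigned} assigned, {report.unassigned} unassigned, "
        f"{report.reads_rejected} rejected, {report.reads_length_filtered} short"
    )
    return profile, report
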