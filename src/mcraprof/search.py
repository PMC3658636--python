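"""Local alignment search with Karlin-Altschul E-values, plus BLAST-tabular interop.

Dereplicated amplicons are scored against the reference database with an
affine-gap Smith-Waterman dynamic program (a gap of length L scores
``gap_open + L * gap_extend``). Raw scores S are converted to expectation
values with ungapped Karlin-Altschul statistics::

    E = K * m * n * exp(-lambda * S)

where m is the query length, n the total residue count of the database, and
lambda the unique positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1
under the assumed base composition p. No effective-length correction is
applied; internal scores only need to be monotone-consistent for top-hit
selection, and the E-value threshold downstream is deliberately conservative.

Users who ran an external BLASTn instead can ingest 12-column tabular output
(``-outfmt 6``, optionally with a subject-title column) via
:func:`parse_blast_tabular`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .errors import ConfigError, DataError
from .iupac import IUPAC_MASKS, normalize, revcomp
from .reference import ReferenceDatabase

#: Published ungapped Karlin-Altschul K for the (+1, -2) nucleotide scheme.
DEFAULT_K = 0.621

_NEG = np.int64(-(2**40))


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch rewards and affine gap penalties (all integer).

    A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
    """

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ConfigError("match_reward must be positive")
        if self.mismatch_penalty >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ConfigError("mismatch/gap penalties must be negative")


@dataclass(frozen=True)
class KarlinAltschulParams:
    """lambda, K and the m x n search space for the E-value formula."""

    lam: float
    k: float
    search_space_m: int
    search_space_n: int

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ConfigError("lambda and K must be positive")
        if self.search_space_m <= 0 or self.search_space_n <= 0:
            raise ConfigError("search-space sizes must be positive")


@dataclass
class LocalAlignment:
    query_name: str
    subject_accession: str
    score: float
    aligned_length: int
    identities: int
    query_span: tuple[int, int]  # 1-based inclusive
    subject_span: tuple[int, int]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.identities > self.aligned_length:
            raise ValueError("identities cannot exceed aligned_length")


@dataclass
class SearchHit:
    alignment: LocalAlignment
    evalue: float
    percent_identity: float
    subject_description: str = ""
    # BLAST-tabular bookkeeping, kept for lossless round-trips.
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be nonnegative")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")

    @property
    def score(self) -> float:
        return self.alignment.score

    @property
    def aligned_length(self) -> int:
        return self.alignment.aligned_length

    @property
    def subject_accession(self) -> str:
        return self.alignment.subject_accession


def solve_lambda(
    scheme: ScoringScheme, base_composition: Sequence[float] | None = None
) -> float:
    """Positive root lambda of sum_ij p_i p_j exp(lambda s_ij) = 1.

    ``base_composition`` gives (pA, pC, pG, pT); uniform by default. Requires
    a negative expected score per aligned pair (the Karlin-Altschul regime);
    raises :class:`ConfigError` otherwise. The residual at the returned root
    is below 1e-9.
    """
    p = np.asarray(base_composition if base_composition is not None else [0.25] * 4)
    if p.shape != (4,) or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ConfigError("base_composition must be 4 nonnegative frequencies summing to 1")
    p_match = float(np.sum(p * p))
    p_mismatch = 1.0 - p_match
    expected = p_match * scheme.match_reward + p_mismatch * scheme.mismatch_penalty
    if expected >= 0:
        raise ConfigError(
            "expected per-pair score must be negative for Karlin-Altschul "
            f"statistics to apply (got {expected:+.4f}); use a harsher mismatch penalty"
        )

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * scheme.match_reward)
            + p_mismatch * math.exp(lam * scheme.mismatch_penalty)
            - 1.0
        )

    hi = 1.0
    while f(hi) <= 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-12, hi, xtol=1e-15, rtol=8.9e-16))
    assert abs(f(lam)) < 1e-9
    return lam


def evalue(score: float, ka_params: KarlinAltschulParams) -> float:
    """Karlin-Altschul expectation: K * m * n * exp(-lambda * score)."""
    return (
        ka_params.k
        * ka_params.search_space_m
        * ka_params.search_space_n
        * math.exp(-ka_params.lam * score)
    )


@njit(cache=False)
def _sw_fill(qmask, smask, match, mismatch, gap_oe, gap_ext):  # pragma: no cover
    m, n = qmask.shape[0], smask.shape[0]
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), _NEG, np.int64)  # gap in query (subject advances)
    F = np.full((m + 1, n + 1), _NEG, np.int64)  # gap in subject (query advances)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_oe
            e2 = E[i, j - 1] + gap_ext
            if e2 > e:
                e = e2
            f = H[i - 1, j] + gap_oe
            f2 = F[i - 1, j] + gap_ext
            if f2 > f:
                f = f2
            s = match if (qmask[i - 1] & smask[j - 1]) != 0 else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


def _encode(seq: str) -> np.ndarray:
    return np.array([IUPAC_MASKS[b] for b in seq], dtype=np.int64)


def _traceback(H, E, F, qmask, smask, scheme, end_i, end_j):
    """Deterministic traceback (diagonal > gap-in-query > gap-in-subject)."""
    gap_oe = scheme.gap_open + scheme.gap_extend
    i, j = end_i, end_j
    cols = 0
    idents = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = (
                scheme.match_reward
                if (qmask[i - 1] & smask[j - 1]) != 0
                else scheme.mismatch_penalty
            )
            if H[i, j] == H[i - 1, j - 1] + s:
                cols += 1
                if (qmask[i - 1] & smask[j - 1]) != 0:
                    idents += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            if E[i, j] == H[i, j - 1] + gap_oe:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # F
            cols += 1
            if F[i, j] == H[i - 1, j] + gap_oe:
                i -= 1
                state = "H"
            else:
                i -= 1
    return i + 1, j + 1, cols, idents  # 1-based starts


def smith_waterman(
    query: str,
    subject: str,
    scheme: ScoringScheme = ScoringScheme(),
    query_name: str = "",
    subject_accession: str = "",
    strand: str = "+",
) -> LocalAlignment:
    """Best-scoring local alignment of ``query`` against ``subject``.

    IUPAC ambiguity codes in the subject count as identities when the query
    base is in their allowed set. Ties among maximal-scoring alignments are
    broken by lowest query start, then lowest subject start (then ends).
    When no positive-scoring alignment exists the result has score 0 and
    empty spans.
    """
    q = normalize(query)
    s = normalize(subject)
    if not q or not s:
        raise DataError("smith_waterman requires non-empty sequences")
    qmask, smask = _encode(q), _encode(s)
    H, E, F = _sw_fill(
        qmask,
        smask,
        np.int64(scheme.match_reward),
        np.int64(scheme.mismatch_penalty),
        np.int64(scheme.gap_open + scheme.gap_extend),
        np.int64(scheme.gap_extend),
    )
    best = int(H.max())
    if best <= 0:
        return LocalAlignment(
            query_name, subject_accession, 0.0, 0, 0, (0, 0), (0, 0), strand
        )
    ends = np.argwhere(H == best)
    candidates = []
    for end_i, end_j in ends:
        qs, ss, cols, idents = _traceback(
            H, E, F, qmask, smask, scheme, int(end_i), int(end_j)
        )
        candidates.append((qs, ss, int(end_i), int(end_j), cols, idents))
    qs, ss, qe, se, cols, idents = min(candidates)
    return LocalAlignment(
        query_name=query_name,
        subject_accession=subject_accession,
        score=float(best),
        aligned_length=cols,
        identities=idents,
        query_span=(qs, qe),
        subject_span=(ss, se),
        strand=strand,
    )


def search_database(
    queries: Iterable[tuple[str, str]],
    db: ReferenceDatabase,
    scheme: ScoringScheme = ScoringScheme(),
    k: float = DEFAULT_K,
    base_composition: Sequence[float] | None = None,
) -> dict[str, list[SearchHit]]:
    """Align each (name, sequence) query to every reference sequence.

    Both query strands are searched (the database is stored in one
    orientation); the better-scoring strand provides the single hit per
    query/subject pair, with the forward strand winning ties. Returns hits
    keyed by query name, unfiltered and sorted by descending score.
    """
    lam = solve_lambda(scheme, base_composition)
    n_total = db.total_residues
    if n_total == 0:
        raise DataError("reference database has no sequences to search")
    out: dict[str, list[SearchHit]] = {}
    for qname, qseq in queries:
        m = len(qseq)
        ka = KarlinAltschulParams(lam=lam, k=k, search_space_m=m, search_space_n=n_total)
        hits: list[SearchHit] = []
        for rec in db:
            if rec.sequence is None:
                continue
            best_aln: LocalAlignment | None = None
            for strand, qs in (("+", qseq), ("-", revcomp(qseq))):
                aln = smith_waterman(
                    qs, rec.sequence, scheme, qname, rec.accession, strand
                )
                if best_aln is None or aln.score > best_aln.score:
                    best_aln = aln
            assert best_aln is not None
            if best_aln.aligned_length == 0:
                continue
            hits.append(
                SearchHit(
                    alignment=best_aln,
                    evalue=evalue(best_aln.score, ka),
                    percent_identity=100.0 * best_aln.identities / best_aln.aligned_length,
                    subject_description=rec.species_label,
                )
            )
        hits.sort(key=lambda h: (-h.score, h.evalue, h.subject_accession))
        out[qname] = hits
    return out


_BLAST_COLS = 12


def parse_blast_tabular(path: str | Path) -> list[SearchHit]:
    """Parse BLAST ``-outfmt 6`` tabular output (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore [stitle])."""
    hits: list[SearchHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _BLAST_COLS:
                raise DataError(
                    f"{path}:{lineno}: expected >= {_BLAST_COLS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            (qseqid, sseqid, pident, length, mismatch, gapopen,
             qstart, qend, sstart, send, ev, bitscore) = fields[:_BLAST_COLS]
            length_i = int(length)
            pid = float(pident)
            sstart_i, send_i = int(sstart), int(send)
            aln = LocalAlignment(
                query_name=qseqid,
                subject_accession=sseqid,
                score=float(bitscore),
                aligned_length=length_i,
                identities=round(pid * length_i / 100.0),
                query_span=(int(qstart), int(qend)),
                subject_span=(sstart_i, send_i),
                strand="+" if send_i >= sstart_i else "-",
            )
            hits.append(
                SearchHit(
                    alignment=aln,
                    evalue=float(ev),
                    percent_identity=pid,
                    subject_description=fields[12] if len(fields) > 12 else sseqid,
                    mismatches=int(mismatch),
                    gap_opens=int(gapopen),
                )
            )
    return hits


def write_hits(hits: Sequence[SearchHit], path: str | Path) -> None:
    """Write hits in the 13-column tabular layout accepted by
    :func:`parse_blast_tabular` (subject title in column 13)."""
    with open(path, "w") as fh:
        for h in hits:
            a = h.alignment
            fh.write(
                "\t".join(
                    [
                        a.query_name,
                        a.subject_accession,
                        f"{h.percent_identity:.2f}",
                        str(a.aligned_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(a.query_span[0]),
                        str(a.query_span[1]),
                        str(a.subject_span[0]),
                        str(a.subject_span[1]),
                        f"{h.evalue:.2e}",
                        f"{a.score:g}",
                        h.subject_description,
                    ]
                )
                + "\n"
            )
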