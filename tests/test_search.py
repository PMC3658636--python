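"""Local alignment, Karlin-Altschul statistics, and BLAST-tabular interop.

The Smith-Waterman implementation is checked along two independent routes:
an explicit enumeration of every gapped alignment of every substring pair
(tiny inputs), and Biopython's PairwiseAligner in local mode (larger random
inputs). Both use the same affine convention: a gap of length L scores
gap_open + L * gap_extend.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

import mcraprof as m
from mcraprof.errors import ConfigError, DataError
from mcraprof.search import ScoringScheme, KarlinAltschulParams

SCHEME = ScoringScheme()  # +1 / -2, gap open -5, gap extend -2


def _enum_global(x, y, scheme):
    """Best affine-gap score aligning all of x to all of y, by enumerating
    every monotone edit script (no DP recurrence shared with the package)."""
    best = -math.inf
    stack = [(0, 0, 0, "start")]
    while stack:
        i, j, score, last = stack.pop()
        if i == len(x) and j == len(y):
            best = max(best, score)
            continue
        if i < len(x) and j < len(y):
            s = scheme.match_reward if x[i] == y[j] else scheme.mismatch_penalty
            stack.append((i + 1, j + 1, score + s, "M"))
        if i < len(x):
            cost = scheme.gap_extend + (0 if last == "D" else scheme.gap_open)
            stack.append((i + 1, j, score + cost, "D"))
        if j < len(y):
            cost = scheme.gap_extend + (0 if last == "I" else scheme.gap_open)
            stack.append((i, j + 1, score + cost, "I"))
    return best


def enum_local_score(q, s, scheme):
    """Brute-force local score: max over all substring pairs, floored at 0."""
    best = 0
    for qs in range(len(q)):
        for qe in range(qs + 1, len(q) + 1):
            for ss in range(len(s)):
                for se in range(ss + 1, len(s) + 1):
                    best = max(best, _enum_global(q[qs:qe], s[ss:se], scheme))
    return best


def _biopython_local_score(q, s, scheme):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match_reward
    aligner.mismatch_score = scheme.mismatch_penalty
    # Biopython scores the first gap position with open_gap_score and the
    # rest with extend_gap_score; map open+extend accordingly.
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    return aligner.score(q, s)


def test_smith_waterman_identical_sequences():
    aln = m.smith_waterman("ACGTACGTAC", "ACGTACGTAC", SCHEME)
    assert (aln.score, aln.aligned_length, aln.identities) == (10, 10, 10)
    assert aln.query_span == (1, 10) and aln.subject_span == (1, 10)


def test_smith_waterman_single_base_best():
    assert m.smith_waterman("ACGT", "CAAA", SCHEME).score == 1


def test_smith_waterman_no_common_base_scores_zero():
    aln = m.smith_waterman("AAAA", "CCCC", SCHEME)
    assert aln.score == 0 and aln.aligned_length == 0


def test_smith_waterman_rejects_empty():
    with pytest.raises(DataError):
        m.smith_waterman("", "ACGT", SCHEME)


def test_smith_waterman_iupac_subject_counts_as_identity():
    aln = m.smith_waterman("ACGT", "ACNT", SCHEME)
    assert aln.score == 4 and aln.identities == 4


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    q=st.text(alphabet="AC", min_size=1, max_size=5),
    s=st.text(alphabet="AC", min_size=1, max_size=5),
)
def test_smith_waterman_matches_enumeration_oracle(q, s):
    assert m.smith_waterman(q, s, SCHEME).score == enum_local_score(q, s, SCHEME)


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    q=st.text(alphabet="AC", min_size=1, max_size=8),
    s=st.text(alphabet="AC", min_size=1, max_size=8),
)
def test_smith_waterman_matches_biopython(q, s):
    assert m.smith_waterman(q, s, SCHEME).score == _biopython_local_score(q, s, SCHEME)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    q=st.text(alphabet="ACGT", min_size=1, max_size=40),
    s=st.text(alphabet="ACGT", min_size=1, max_size=40),
)
def test_smith_waterman_symmetric_score(q, s):
    assert (
        m.smith_waterman(q, s, SCHEME).score == m.smith_waterman(s, q, SCHEME).score
    )


def test_solve_lambda_reproduces_known_constant():
    lam = m.solve_lambda(SCHEME)
    # Root of (1/4) e^lam + (3/4) e^(-2 lam) = 1, the classic +1/-2 value.
    assert lam == pytest.approx(1.33, abs=0.005)
    residual = 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) - 1
    assert abs(residual) < 1e-9


def test_solve_lambda_plus_one_minus_one():
    scheme = ScoringScheme(match_reward=1, mismatch_penalty=-1)
    lam = m.solve_lambda(scheme)
    residual = 0.25 * math.exp(lam) + 0.75 * math.exp(-lam) - 1
    assert lam > 0 and abs(residual) < 1e-9


def test_solve_lambda_requires_negative_expectation():
    with pytest.raises(ConfigError, match="negative"):
        m.solve_lambda(ScoringScheme(match_reward=9, mismatch_penalty=-1))


def test_evalue_formula_properties():
    ka = KarlinAltschulParams(lam=1.33, k=0.621, search_space_m=100, search_space_n=1000)
    assert m.evalue(0, ka) == pytest.approx(0.621 * 100 * 1000)
    ka2 = KarlinAltschulParams(lam=1.33, k=0.621, search_space_m=100, search_space_n=2000)
    assert m.evalue(50, ka2) == pytest.approx(2 * m.evalue(50, ka))
    scores = [0, 10, 20, 40]
    evs = [m.evalue(s, ka) for s in scores]
    assert evs == sorted(evs, reverse=True)


def test_internal_search_on_clean_reads(tagged_primers, mock_db, clean_run):
    """Error-free amplicons align at 100% identity to their source, with
    E-values far below the downstream threshold."""
    _, reads, truth = clean_run
    bins, _ = m.demultiplex(reads, tagged_primers)
    uniques = m.dereplicate(bins["ML"], "ML")[:2]
    hits = m.search_database([(u.name, u.sequence) for u in uniques], mock_db)
    counts = truth[truth.primer_name == "ML"].groupby("source_accession").size()
    for u in uniques:
        top = hits[u.name][0]
        assert top.percent_identity == 100.0
        assert top.evalue < 1e-6
        assert top.aligned_length == len(u.sequence)
        # the read's source is the unique top accession
        assert counts[top.subject_accession] == u.count


def _round_trip_file(tmp_path):
    lines = [
        "ML_0001_946\tCP002565.1\t99.20\t470\t3\t1\t1\t470\t101\t570\t1.00e-180\t850\tMethanosaeta concilii GP-6",
        "MCR_0002_12\tAB551869.1\t97.50\t120\t3\t0\t1\t120\t200\t81\t2.50e-40\t180\tMethanobacterium kanagiense 169",
    ]
    path = tmp_path / "hits.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_parse_blast_tabular_fields(tmp_path):
    hits = m.parse_blast_tabular(_round_trip_file(tmp_path))
    h = hits[0]
    assert h.percent_identity == 99.20
    assert h.aligned_length == 470
    assert h.alignment.score == 850
    assert h.subject_description == "Methanosaeta concilii GP-6"
    assert hits[1].alignment.strand == "-"


def test_parse_blast_tabular_round_trip(tmp_path):
    path = _round_trip_file(tmp_path)
    out = tmp_path / "again.tsv"
    from mcraprof.search import write_hits

    write_hits(m.parse_blast_tabular(path), out)
    assert out.read_text() == path.read_text()


def test_parse_blast_tabular_empty_and_errors(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    assert m.parse_blast_tabular(empty) == []
    bad = tmp_path / "bad.tsv"
    bad.write_text("only\tfour\tcolumns\there\n")
    with pytest.raises(DataError, match=":1"):
        m.parse_blast_tabular(bad)
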