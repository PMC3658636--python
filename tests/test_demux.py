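"""Tag demultiplexing, degenerate primer localisation, and the length filter."""

import pytest
from hypothesis import given, settings, strategies as st

import mcraprof as m
from mcraprof.demux import DemuxedRead, PrimerSet, find_primer
from mcraprof.errors import ConfigError
from mcraprof.iupac import iupac_match, revcomp


@pytest.mark.parametrize(
    "pattern, base, expected",
    [("R", "A", True), ("R", "G", True), ("R", "C", False), ("N", "T", True),
     ("M", "C", True), ("W", "G", False)],
)
def test_iupac_match(pattern, base, expected):
    assert iupac_match(pattern, base) is expected


def test_iupac_match_rejects_non_codes():
    with pytest.raises(ValueError):
        iupac_match("Z", "A")


MLF = "GGTGGTGTMGGATTCACACARTAYGCWACAGC"


def test_find_primer_resolved_degenerate_start():
    read = "GGTGGTGTAGGATTCACACAGTATGCAACAGC" + "TTTT"
    assert find_primer(read, MLF, 0) == (0, "+")


def test_find_primer_single_substitution_misses_at_zero_budget():
    read = "GGTGGTGTAGGATTCACACAGTATGCAACAGC" + "TTTT"
    corrupted = "C" + read[1:]
    assert find_primer(corrupted, MLF, 0) is None
    assert find_primer(corrupted, MLF, 1) == (0, "+")


def _oracle_find(sequence, primer, max_mismatches):
    """Exhaustive scan over all (position, strand) pairs via iupac_match."""
    pat = primer.upper()
    for strand in "+-":
        s = sequence.upper() if strand == "+" else revcomp(sequence)
        for i in range(len(s) - len(pat) + 1):
            mm = sum(
                not iupac_match(p, b) for p, b in zip(pat, s[i : i + len(pat)])
            )
            if mm <= max_mismatches:
                return (i, strand)
    return None


@settings(derandomize=True, max_examples=150)
@given(
    seq=st.text(alphabet="ACGT", min_size=0, max_size=50),
    primer=st.text(alphabet="ACGTRYMWKN", min_size=1, max_size=8),
    budget=st.integers(min_value=0, max_value=2),
)
def test_find_primer_matches_exhaustive_oracle(seq, primer, budget):
    assert find_primer(seq, primer, budget) == _oracle_find(seq, primer, budget)


def _primer_sets():
    return [
        PrimerSet("ML", MLF, "TTCATTGCRTAGTTWGGRTAGTT", "AAAACCCCGG", 470),
        PrimerSet("MCR", "TAYGAYCARATHTGGYT", "ACRTTCATNGCRTARTT", "GGGGTTTTAA", 500),
    ]


def test_demultiplex_partitions_and_strips_tags():
    sets = _primer_sets()
    reads = [
        ("r1", "AAAACCCCGG" + "ACGT" * 10),
        ("r2", "ggggttttaa" + "ACGT" * 10),  # lowercase input
        ("r3", "TTTTTTTTTT" + "ACGT" * 10),  # unknown tag
    ]
    bins, rejects = m.demultiplex(reads, sets)
    assert [r.read_id for r in bins["ML"]] == ["r1"]
    assert [r.read_id for r in bins["MCR"]] == ["r2"]
    assert bins["ML"][0].sequence == "ACGT" * 10
    assert bins["ML"][0].original_length == 50
    assert [rid for rid, _ in rejects] == ["r3"]
    total = sum(len(rs) for rs in bins.values()) + len(rejects)
    assert total == len(reads)


def test_demultiplex_duplicate_tags_is_config_error():
    sets = _primer_sets()
    sets[1].mid_tag = sets[0].mid_tag
    with pytest.raises(ConfigError, match="duplicate"):
        m.demultiplex([("r1", "ACGT" * 5)], sets)


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.text(alphabet="ACGT", min_size=0, max_size=30), min_size=0, max_size=20
    )
)
def test_demultiplex_conserves_reads(seqs):
    reads = [(f"r{i}", s) for i, s in enumerate(seqs)]
    bins, rejects = m.demultiplex(reads, _primer_sets())
    binned_ids = [r.read_id for rs in bins.values() for r in rs]
    reject_ids = [rid for rid, _ in rejects]
    assert sorted(binned_ids + reject_ids) == sorted(rid for rid, _ in reads)


def _read(n):
    return DemuxedRead(read_id=f"len{n}", primer_name="ML", sequence="A" * n,
                       original_length=n + 10)


def test_length_filter_boundary_is_strict():
    kept, discarded = m.length_filter([_read(100), _read(101), _read(20)])
    assert [r.read_id for r in kept] == ["len101"]
    assert [r.read_id for r in discarded] == ["len100", "len20"]


def test_length_filter_discards_exactly_the_dimers(tagged_primers, mock_db):
    config = m.SimulationConfig(
        seed=3,
        n_reads_per_primer={"ML": 50},
        abundances={"MOCK0001.1": 1.0},
        dimer_fraction=0.2,
    )
    reads, truth = m.generate_reads(mock_db, tagged_primers, config)
    bins, rejects = m.demultiplex(reads, tagged_primers)
    assert not rejects
    kept, discarded = m.length_filter(bins["ML"])
    assert len(discarded) == int(truth.is_dimer.sum()) == 10
    assert {r.read_id for r in discarded} == set(truth[truth.is_dimer].read_id)
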