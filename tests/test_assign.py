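"""Hit filtering thresholds, top-hit selection, and count-weighted tallies."""

import pytest

import mcraprof as m
from mcraprof.assign import FilterConfig
from mcraprof.reference import ReferenceRecord, UNASSIGNED_LABEL
from mcraprof.search import LocalAlignment, SearchHit


def _hit(score=500, evalue=1e-50, length=400, pident=99.0, acc="ACC1",
         desc="Methanosaeta concilii GP-6"):
    identities = round(pident * length / 100)
    return SearchHit(
        alignment=LocalAlignment("q", acc, score, length, identities,
                                 (1, length), (1, length)),
        evalue=evalue,
        percent_identity=pident,
        subject_description=desc,
    )


def _unique(name="ML_0001_5", count=5):
    return m.UniqueSequence(name=name, primer_name="ML", sequence="A" * 120,
                            count=count, member_ids=[f"r{i}" for i in range(count)])


@pytest.mark.parametrize(
    "hit, kept",
    [
        (_hit(length=49, evalue=1e-50), False),   # below minimum alignment span
        (_hit(length=50), True),                  # boundary is inclusive
        (_hit(evalue=1e-6), False),               # threshold is strict
        (_hit(evalue=9.9e-7), True),
        (_hit(pident=96.9), False),
        (_hit(desc="Uncultured archaeon clone B-23"), False),
    ],
)
def test_filter_hits_thresholds(hit, kept):
    survivors = m.filter_hits([hit], FilterConfig())
    assert (len(survivors) == 1) is kept


def test_filter_hits_uses_annotation_uncultured_flag():
    rec = ReferenceRecord(accession="ACC1", species_label="Environmental clone X",
                          order="NA", uncultured=True)
    hit = _hit(desc="clone X")
    assert m.filter_hits([hit], FilterConfig(), {"ACC1": rec}) == []
    assert m.filter_hits([hit], FilterConfig(exclude_keywords=()), {"ACC1": rec}) == [hit]


def test_filter_monotone_in_thresholds():
    hits = [_hit(length=L, evalue=e, pident=p)
            for L in (50, 60) for e in (1e-10, 1e-7) for p in (97.0, 99.5)]
    base = len(m.filter_hits(hits, FilterConfig()))
    tighter = [
        FilterConfig(min_alignment_bp=55),
        FilterConfig(max_evalue=1e-8),
        FilterConfig(min_percent_identity=98.0),
    ]
    for cfg in tighter:
        assert len(m.filter_hits(hits, cfg)) <= base


def test_assign_top_hit_picks_max_score():
    rec = m.assign_top_hit(_unique(), [_hit(score=790, acc="B"), _hit(score=850, acc="A")])
    assert rec.assigned_accession == "A"
    assert rec.is_assigned


def test_assign_top_hit_empty_is_unassigned():
    rec = m.assign_top_hit(_unique(), [])
    assert rec.assigned_species == UNASSIGNED_LABEL
    assert rec.assigned_accession is None and rec.best_hit is None


def test_assign_top_hit_tie_breaks_on_accession():
    rec = m.assign_top_hit(_unique(), [_hit(acc="AB1"), _hit(acc="AA9")])
    assert rec.assigned_accession == "AA9"


def test_assign_top_hit_prefers_lower_evalue_then_identity():
    rec = m.assign_top_hit(
        _unique(), [_hit(acc="X", evalue=1e-40), _hit(acc="Y", evalue=1e-50)]
    )
    assert rec.assigned_accession == "Y"
    rec = m.assign_top_hit(
        _unique(), [_hit(acc="X", pident=98.0), _hit(acc="Y", pident=99.5)]
    )
    assert rec.assigned_accession == "Y"


def test_tally_weights_by_dereplication_count():
    records = [
        m.assign_top_hit(_unique("ML_0001_3", 3), [_hit()]),
        m.assign_top_hit(_unique("ML_0002_2", 2), [_hit()]),
        m.assign_top_hit(_unique("ML_0003_4", 4), []),
    ]
    counts, unassigned = m.tally(records)
    assert counts == {"Methanosaeta concilii GP-6": 5}
    assert unassigned == 4
    assert sum(counts.values()) + unassigned == 9


def test_single_record_contributes_its_count():
    counts, unassigned = m.tally([m.assign_top_hit(_unique(count=5), [_hit()])])
    assert counts == {"Methanosaeta concilii GP-6": 5} and unassigned == 0


def test_decoy_immunity(tagged_primers, mock_db, clean_run):
    """An uncultured decoy identical to a real reference flips assignments only
    when keyword exclusion is disabled."""
    _, reads, truth = clean_run
    bins, _ = m.demultiplex(reads, tagged_primers)
    uniques = m.dereplicate(bins["ML"], "ML")[:1]
    top_source = (
        truth[truth.primer_name == "ML"].groupby("source_accession").size().idxmax()
    )
    real = mock_db[top_source]
    decoy = ReferenceRecord(
        accession="AAAA0001.1",  # sorts before every mock accession
        species_label="Uncultured archaeon clone B-23",
        order="NA",
        uncultured=True,
        sequence=real.sequence,
    )
    db2 = m.ReferenceDatabase(list(mock_db) + [decoy])
    ann = {rec.accession: rec for rec in db2}
    hits = m.search_database([(u.name, u.sequence) for u in uniques], db2)

    records = m.assign_all(uniques, hits, FilterConfig(), ann)
    assert records[0].assigned_accession == top_source

    records_open = m.assign_all(uniques, hits, FilterConfig(exclude_keywords=()), ann)
    assert records_open[0].assigned_accession == "AAAA0001.1"
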