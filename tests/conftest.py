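import numpy as np
import pytest

import mcraprof as m


@pytest.fixture(scope="session")
def fixture_tally():
    """The bundled anaerobic-digester mcrA hit tally."""
    return m.load_tally_fixture()


@pytest.fixture(scope="session")
def tagged_primers():
    rng = np.random.default_rng(12345)
    return m.assign_tags(m.load_primer_sets(), rng)


@pytest.fixture(scope="session")
def mock_db(tagged_primers):
    rng = np.random.default_rng(99)
    return m.build_mock_community(tagged_primers, 4, rng)


@pytest.fixture(scope="session")
def clean_run(tagged_primers, mock_db):
    """Error-free, dimer-free synthetic reads plus their truth table."""
    config = m.SimulationConfig(
        seed=7,
        n_reads_per_primer={"ML": 40, "MCR": 40, "ME": 20},
        abundances={
            "MOCK0001.1": 4.0,
            "MOCK0002.1": 2.0,
            "MOCK0003.1": 1.0,
            "MOCK0004.1": 1.0,
        },
    )
    reads, truth = m.generate_reads(mock_db, tagged_primers, config)
    return config, reads, truth
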