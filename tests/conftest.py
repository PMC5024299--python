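import numpy as np
import pytest

import selexmer as sx


@pytest.fixture(scope="session")
def design():
    return sx.OligoDesign()


@pytest.fixture(scope="session")
def pho4_model():
    """Synthetic stand-in for a bHLH factor: E-box consensus, 5x per-mismatch penalty."""
    return sx.BindingModel("CACGTG", 5.0)


@pytest.fixture(scope="session")
def small_run(design, pho4_model):
    """3 selection rounds at 20k reads/round; big enough for consensus recovery."""
    return sx.simulate_rounds(design, pho4_model, n_rounds=3, reads_per_round=20_000, rng_seed=11)


@pytest.fixture(scope="session")
def small_run_tables(small_run):
    tables = []
    for r, coll in enumerate(small_run.rounds):
        t = sx.count_kmers(coll, 6)
        t.round_index = r
        tables.append(t)
    return tables


def filtered_from_collection(coll, round_index=0):
    """Wrap a simulated ReadCollection as an already-filtered insert multiset."""
    fs = sx.FilteredReadSet(round_index, coll.design.barcodes[0], coll.design.insert_length)
    for ins in coll.insert_strings():
        fs.inserts[ins] += 1
    fs.n_input = len(coll)
    return fs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
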