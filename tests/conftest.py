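import numpy as np
import pytest

from oralmia.io_tables import OtuTable, metadata_frame
from oralmia.synthdata import SynthConfig, generate_study, generate_tree


@pytest.fixture
def tiny_table():
    """3 OTUs x 2 samples, hand-written."""
    return OtuTable(
        ["OTU001", "OTU002", "OTU003"],
        ["S1", "S2"],
        np.array([[2, 10], [3, 0], [5, 30]]),
        {"OTU001": "P1;C1;O1;F1;G1;G1 sp1", "OTU002": "P1;C1;O1;F1;G1;G1 sp2"},
    )


@pytest.fixture(scope="session")
def small_study():
    """Two-habitat study with planted signal, shared by several test modules."""
    config = SynthConfig(
        n_otus=80,
        group_sizes={
            ("control", "saliva"): 12,
            ("ASD", "saliva"): 12,
            ("control", "plaque"): 10,
            ("ASD", "plaque"): 10,
        },
        depth_mean=8000.0,
        depth_sd=800.0,
        n_diff_per_habitat=10,
        log2_fold_change=3.0,
        cooc_block_size=4,
        seed=42,
    )
    table, records, tree, truth = generate_study(config)
    return {
        "config": config,
        "table": table,
        "records": records,
        "meta": metadata_frame(records),
        "tree": tree,
        "truth": truth,
    }


@pytest.fixture
def random_tree_factory():
    def make(n_leaves: int, seed: int):
        ids = [f"L{i}" for i in range(n_leaves)]
        return ids, generate_tree(ids, seed=seed)

    return make
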