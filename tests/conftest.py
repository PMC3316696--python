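import numpy as np
import pytest

import coikit as ck


@pytest.fixture(scope="session")
def small_config():
    return ck.SimConfig(
        n_families=3,
        genera_per_family=2,
        species_per_genus=3,
        samples_per_species=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """18-record, 3-family synthetic alignment with ground truth."""
    return ck.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    """Distance matrices, NJ tree and 50-rep bootstrap for the small dataset."""
    alignment, truth = small_dataset
    dm_k2p = ck.distance_matrix(alignment, model="k2p")
    dm_p = ck.distance_matrix(alignment, model="p")
    tree = ck.neighbor_joining(dm_k2p)
    annotated, support, dropped = ck.bootstrap_support(alignment, "k2p", tree, 50, 123)
    return {
        "alignment": alignment,
        "truth": truth,
        "dm_k2p": dm_k2p,
        "dm_p": dm_p,
        "tree": tree,
        "annotated": annotated,
        "support": support,
        "dropped": dropped,
    }
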