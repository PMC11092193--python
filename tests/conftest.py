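import numpy as np
import pytest

import ffane


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial synthetic attributed network (60 proteins)."""
    config = ffane.SyntheticConfig(
        n_proteins=60, n_communities=3, p_in=0.3, p_out=0.03,
        ancestor_length=40, seed=7,
    )
    return ffane.generate_dataset(config)


@pytest.fixture(scope="session")
def small_similarities(small_dataset):
    proteins, network, _ = small_dataset
    s_net = ffane.gip_similarity(network)
    s_seq = ffane.sequence_similarity_matrix(proteins)
    return s_net, s_seq


@pytest.fixture
def toy_proteins():
    return ffane.ProteinSet(
        ids=("p1", "p2", "p3"),
        sequences={"p1": "MKT", "p2": "MAT", "p3": "WYF"},
    )


@pytest.fixture
def path_network():
    """3-node path graph: profiles (0,1,0), (1,0,1), (0,1,0)."""
    return ffane.InteractionNetwork(
        adjacency=np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    )
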