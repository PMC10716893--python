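import numpy as np
import pytest

from moltreegen import FeatureConfig, GraphVAE, make_fixture_set
from moltreegen.vgae import DecodedFeatureMap


@pytest.fixture(scope="session")
def config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def fixture_smiles():
    return make_fixture_set(50, seed=1)


@pytest.fixture(scope="session")
def tiny_model(fixture_smiles):
    """A briefly trained auto-encoder shared by search/pipeline tests."""
    model = GraphVAE(epochs=3, seed=0)
    model.fit(fixture_smiles[:30])
    return model


def toy_feature_map(edge_prob, n_slots=5, d_node=None, carbon_bias=5.0):
    """A small decoded map with carbon-favoring node scores for tests."""
    cfg = FeatureConfig()
    d_node = d_node or cfg.n_node_features
    p = np.zeros((n_slots, n_slots))
    for (i, j), v in edge_prob.items():
        p[i, j] = p[j, i] = v
    node = np.zeros((n_slots, d_node))
    node[:, cfg.element_index("C")] = carbon_bias
    return DecodedFeatureMap(edge_prob=p, node_map=node)


@pytest.fixture
def chain_map():
    """5 slots wired as a path 0-1-2-3-4 with strong edges."""
    return toy_feature_map({(0, 1): 0.9, (1, 2): 0.8, (2, 3): 0.7, (3, 4): 0.6})
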