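import pytest

from smrwalk.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale study conditions used across tests."""
    return SimulationConfig(n_genes=40, n_snps_per_gene=5, n_causal_genes=8,
                            module_size=16, n_seed_genes=8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(gwas, eqtl, network, truth) for the small synthetic study."""
    return simulate_all(small_cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 240-gene network, 60-gene planted
    module, 34 seed genes, 45 causal genes."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_embedding(default_dataset):
    """Random-walk encoding of the default network (shared across tests;
    the encoder itself is deterministic under the pinned seed)."""
    from smrwalk.rw_encoder import RwConfig, encode_network
    _, _, net, _ = default_dataset
    return encode_network(net, RwConfig(dim=16, seed=7))
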