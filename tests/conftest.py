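import pytest

from chipbit2.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 300 kb toy genome with 16 planted peaks; shared across fast tests."""
    config = SimConfig(
        genome=[("chr1", 300_000)],
        n_strong=8,
        n_weak=8,
        sample_depth=30_000,
        input_depth=30_000,
        n_decoy_genes=10,
        n_decoy_enhancers=10,
        seed=7,
    )
    paths, truth = simulate(config, tmp_path_factory.mktemp("smallsim"))
    return config, paths, truth
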