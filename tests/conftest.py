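import pytest

from hmlnet.synthetic_data import SimulationConfig, write_fixture_dir


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """One complete synthetic study (default = study-condition preset)."""
    outdir = tmp_path_factory.mktemp("study")
    config = SimulationConfig(seed=7)
    paths, truth = write_fixture_dir(config, outdir)
    return config, paths, truth


@pytest.fixture(scope="session")
def small_config():
    """A reduced study for fast regeneration inside individual tests."""
    return SimulationConfig(
        seed=11,
        n_mrnas=300,
        n_lncrnas=40,
        n_pathways=8,
        pathway_size=20,
        n_background_edges=60,
        hub_extra_degrees=(15, 10, 6, 3, 2),
    )
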