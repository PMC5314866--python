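import pytest

from methylmirror.simulate import SimConfig, generate_cohort, generate_manifest


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_probes=3000, seed=11,
                     fraction_shared_effects=0.02,
                     fraction_tissue_specific_effects=0.02)


@pytest.fixture(scope="session")
def manifest(sim_config):
    return generate_manifest(sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config, manifest):
    return generate_cohort(manifest, sim_config)
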