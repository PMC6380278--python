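import numpy as np
import pytest

from editqtl import sim


@pytest.fixture(scope="session")
def discovery_bundle():
    """Planted discovery cohort: edits, germline SNPs, filter decoys."""
    return sim.simulate_discovery(seed=0)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale quantification cohort configuration."""
    return sim.SimConfig(
        n_animals=120,
        n_founders=30,
        n_generations=2,
        n_variants=150,
        n_edit_sites=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Pedigree, genotypes and editing counts at desk scale."""
    rng = np.random.default_rng(small_config.seed)
    ped = sim.simulate_pedigree(small_config, rng)
    geno = sim.simulate_genotypes(ped, small_config, rng)
    edit = sim.simulate_editing(geno.dosages, ped, small_config, rng)
    return ped, geno, edit
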