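import numpy as np
import pytest

from hibernaseq.core import make_design
from hibernaseq.simulate import SimConfig, SplicingSim, build_genome, simulate_nascent

NASCENT_STATES = ("SA", "IBA", "Ent", "ET", "LT")
EXT_TRUTH = {"SA": (0, 0), "IBA": (0, 0), "Ent": (300, 0), "ET": (600, 0), "LT": (2500, 0)}


@pytest.fixture(scope="session")
def det_config():
    """Deterministic no-noise config used as exact-recovery oracle."""
    return SimConfig(
        n_chromosomes=2,
        chrom_length=120_000,
        n_genes=12,
        gene_length_range=(2000, 3000),
        intergenic_gap_range=(4000, 7000),
        states=NASCENT_STATES,
        replicates_per_state=3,
        seed=7,
        extension_truth=dict(EXT_TRUTH),
        background_rate=0.0,
        deterministic=True,
        # depth high enough that the injected 0.3 PSI shift clears the
        # 0.2 / 99.9% posterior criterion with room to spare
        splicing=SplicingSim(depth=400),
    )


@pytest.fixture(scope="session")
def det_genome(det_config):
    return build_genome(det_config)


@pytest.fixture(scope="session")
def det_design(det_config):
    return make_design(det_config.states, det_config.replicates_per_state)


@pytest.fixture(scope="session")
def det_tracks(det_config, det_genome, det_design):
    _, genes, truth = det_genome
    return simulate_nascent(genes, truth, det_design, det_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
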