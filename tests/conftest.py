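import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oometh as om

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_cell(cell_id, sites, condition=None):
    """Cell from {chrom: (positions, meth, unmeth)} given as plain lists."""
    return om.SingleCellMethylome(
        cell_id,
        {
            chrom: (np.asarray(p), np.asarray(m), np.asarray(u))
            for chrom, (p, m, u) in sites.items()
        },
        condition=condition,
    )


def cell_from_states(cell_id, states, chrom="chr1", start=0, spacing=10, condition=None):
    """Cell with one call per CpG from a 0/1 state vector."""
    states = np.asarray(states)
    pos = start + spacing * np.arange(len(states))
    return make_cell(cell_id, {chrom: (pos, states, 1 - states)}, condition=condition)


@pytest.fixture(scope="session")
def small_config():
    return om.SimConfig(
        seed=101,
        n_chromosomes=2,
        n_cpgs=40_000,
        x_cpgs=4_000,
        cells_per_condition=12,
        coverage=0.2,
        n_spiked_tiles=8,
        effect_size=0.30,
        n_x_cgis=8,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(genome, cells, truth) for a small two-condition methylome simulation."""
    return om.simulate_methylomes(small_config)


@pytest.fixture(scope="session")
def small_tiles(small_sim):
    genome, _, _ = small_sim
    return om.make_tiles(genome)
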