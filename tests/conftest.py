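"""Shared fixtures: one small simulated population reused across modules.

The simulated genome is scaled down (300 kb, 60 kb island) so the whole
suite stays fast; per-bp rates, category proportions, coverages and error
models are the full-scale study conditions.
"""

from __future__ import annotations

import pytest

from magpop.simulate import (
    SimConfig,
    simulate_genome,
    simulate_population,
    simulate_reads,
    write_truth,
)

SMALL_L = 300_000
SMALL_SY = (30_000, 90_000)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11).scaled(SMALL_L, *SMALL_SY)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    genome, _ = simulate_genome(small_cfg)
    population = simulate_population(genome, small_cfg)
    return genome, population


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_sim, tmp_path_factory):
    """Genome + population + reads + truth files on disk."""
    genome, population = small_sim
    outdir = tmp_path_factory.mktemp("simdata")
    paths = write_truth(genome, population, outdir)
    reads = simulate_reads(genome, population, small_cfg, outdir)
    return {
        "config": small_cfg,
        "genome": genome,
        "population": population,
        "paths": paths,
        "reads": reads,
        "outdir": outdir,
    }
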