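"""Shared fixtures: one small simulated hybrid-trio dataset per session."""

import pytest

import methylcross as mc


@pytest.fixture(scope="session")
def small_cfg() -> mc.SimulationConfig:
    return mc.SimulationConfig(
        seed=11,
        genome_length=150_000,
        n_te_per_class=6,
        n_families=8,
        n_genes=10,
        chloroplast_length=8_000,
        n_spiked_dmrs=4,
    )


@pytest.fixture(scope="session")
def pair(small_cfg) -> mc.GenomePair:
    return mc.simulate_genome_pair(small_cfg)


@pytest.fixture(scope="session")
def methylomes(small_cfg, pair) -> mc.MethylomeSet:
    return mc.simulate_methylomes(pair, small_cfg)


@pytest.fixture(scope="session")
def contexts_ref_a(pair):
    return mc.assign_contexts(pair.sequences["A"])
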