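"""Shared fixtures: small seeded genomes and experiments.

All simulation fixtures are generated programmatically at test time; sizes
are kept small so the default run stays fast.
"""

from __future__ import annotations

import pytest

import hapdrive as hd


@pytest.fixture(scope="session")
def small_genome():
    """2 chromosomes x 2 Mb, 40 genes — enough structure for every region
    class (exon/intron/splice/intragenic/intergenic/diploid)."""
    return hd.generate_genome(
        n_chromosomes=2, n_genes=40, chrom_length=2_000_000, seed=42
    )


@pytest.fixture(scope="session")
def small_experiment(small_genome):
    """Two drugs x two selections with one dependent lineage, light
    passenger load; used by I/O and funnel tests."""
    config = hd.SimExperimentConfig(
        drugs=("GEM", "TPT"),
        selections_per_drug=2,
        dependent_groups={"TPT-R2": ["TPT-R2a", "TPT-R2b"]},
        passenger_model=hd.PassengerModel(rate=120),
        assays={"GEM-R2": "WES"},
        seed=42,
    )
    return hd.simulate_experiment(small_genome, config)


def pytest_addoption(parser):  # placeholder to keep CLI tidy
    pass
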