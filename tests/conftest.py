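"""Shared fixtures: small simulated histories used across the test modules."""

from __future__ import annotations

import pytest

from wgdlab import homology, simulate, synteny
from wgdlab.genome import Gene, Genome


def make_genome(species: str, chrom_sizes: dict[str, int], cds: str | None = None) -> Genome:
    """Hand-built genome with sequential gene ids, optionally one shared CDS."""
    chroms = {}
    counter = 0
    for chrom, n in chrom_sizes.items():
        genes = []
        for r in range(n):
            genes.append(
                Gene(
                    id=f"{species}_g{counter:05d}",
                    chromosome=chrom,
                    order=r,
                    start=r * 10000,
                    end=r * 10000 + 300,
                    cds=cds,
                )
            )
            counter += 1
        chroms[chrom] = genes
    return Genome(species=species, chromosomes=chroms)


@pytest.fixture(scope="session")
def one_wgd_fast():
    """Fast-mode genome after one WGD (no loss): 2 copies per ancestral gene."""
    cfg = simulate.SimConfig(
        n_chromosomes=3,
        genes_per_chromosome=60,
        codons_per_gene=100,
        schedule=[simulate.TimedEvent(30.0, "anc", "wgd", {"loss": 0.0})],
        seed=7,
        mode="ks_level",
    )
    genomes, truth = simulate.simulate_evolution(cfg)
    return cfg, genomes["anc"], truth


@pytest.fixture(scope="session")
def two_wgd_vs_sister_fast():
    """Focal lineage with shared + private WGD vs a sister with the shared WGD only."""
    cfg = simulate.SimConfig(
        n_chromosomes=3,
        genes_per_chromosome=60,
        codons_per_gene=100,
        rate_r=4.29e-9,
        schedule=[
            simulate.TimedEvent(122.31, "anc", "wgd", {"loss": 0.0}),
            simulate.TimedEvent(98.55, "anc", "speciation", {"children": ["focal", "sister"]}),
            simulate.TimedEvent(15.14, "focal", "wgd", {"loss": 0.0}),
        ],
        seed=5,
        mode="ks_level",
    )
    genomes, truth = simulate.simulate_evolution(cfg)
    return cfg, genomes, truth


def blocks_between(truth, genome_a, genome_b, max_gap=25, min_anchors=5):
    pairs = homology.pairs_from_truth(truth, genome_a, genome_b)
    anchors, _ = synteny.build_anchors(pairs, genome_a, genome_b)
    return synteny.chain_anchors(anchors, max_gap, min_anchors)
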