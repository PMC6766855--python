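"""Shared fixtures: small simulated experiments and toy annotation inputs.

Everything is generated programmatically; nothing is read from checked-in
data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from poolscan import (
    LibraryMeta,
    NucleotideCounts,
    SimulationConfig,
    SiteKey,
    SiteRecord,
    SiteTable,
    default_gene_layout,
    simulate_experiment,
)


LIBS = [
    LibraryMeta("res_1", "resistant", 1),
    LibraryMeta("res_2", "resistant", 2),
    LibraryMeta("sus_1", "susceptible", 1),
    LibraryMeta("sus_2", "susceptible", 2),
]


def make_record(chrom, pos, ref, per_lib):
    counts = {
        lib.id: None if c is None else NucleotideCounts(*c)
        for lib, c in zip(LIBS, per_lib)
    }
    return SiteRecord(SiteKey(chrom, pos, ref), counts)


@pytest.fixture
def libraries():
    return list(LIBS)


@pytest.fixture(scope="session")
def mini_config():
    """A small, fully annotatable experiment: short chromosomes so a
    reference FASTA can be written quickly."""
    layout = default_gene_layout(
        n_chromosomes=3,
        chromosome_length=60_000,
        genes_per_chromosome=6,
        gene_length=3_000,
    )
    return SimulationConfig(
        seed=5,
        sites_per_chromosome=300,
        chromosome_length=60_000,
        gene_layout=layout,
        linked_block_size=20_000,
        depth_mean=80.0,
        depth_dispersion=None,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def mini_experiment(mini_config):
    return simulate_experiment(mini_config)


@pytest.fixture(scope="session")
def default_experiment():
    """One default-scale experiment reused by recovery-style tests."""
    return simulate_experiment(SimulationConfig(seed=0))


@pytest.fixture
def toy_gff3(tmp_path):
    """Two-exon plus-strand gene, a minus-strand gene with flanking UTRs,
    and an ncRNA gene."""
    text = """##gff-version 3
chr1\ttoy\tgene\t1001\t2000\t.\t+\t.\tID=geneA
chr1\ttoy\tmRNA\t1001\t2000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttoy\texon\t1001\t1400\t.\t+\t.\tID=geneA.e1;Parent=geneA.t1
chr1\ttoy\texon\t1601\t2000\t.\t+\t.\tID=geneA.e2;Parent=geneA.t1
chr1\ttoy\tfive_prime_UTR\t1001\t1100\t.\t+\t.\tID=geneA.u5;Parent=geneA.t1
chr1\ttoy\tCDS\t1101\t1400\t.\t+\t0\tID=geneA.c1;Parent=geneA.t1
chr1\ttoy\tCDS\t1601\t1900\t.\t+\t0\tID=geneA.c2;Parent=geneA.t1
chr1\ttoy\tthree_prime_UTR\t1901\t2000\t.\t+\t.\tID=geneA.u3;Parent=geneA.t1
chr1\ttoy\tgene\t5001\t6000\t.\t-\t.\tID=geneB
chr1\ttoy\tmRNA\t5001\t6000\t.\t-\t.\tID=geneB.t1;Parent=geneB
chr1\ttoy\texon\t5001\t6000\t.\t-\t.\tID=geneB.e1;Parent=geneB.t1
chr1\ttoy\tthree_prime_UTR\t5001\t5100\t.\t-\t.\tID=geneB.u3;Parent=geneB.t1
chr1\ttoy\tCDS\t5101\t5901\t.\t-\t0\tID=geneB.c1;Parent=geneB.t1
chr1\ttoy\tfive_prime_UTR\t5902\t6000\t.\t-\t.\tID=geneB.u5;Parent=geneB.t1
chr2\ttoy\tgene\t100\t400\t.\t+\t.\tID=geneC
chr2\ttoy\tncRNA\t100\t400\t.\t+\t.\tID=geneC.nc;Parent=geneC
"""
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path


@pytest.fixture
def toy_categories(tmp_path):
    path = tmp_path / "categories.tsv"
    path.write_text("geneA\tCYP\ngeneB\tneuro\n")
    return path
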