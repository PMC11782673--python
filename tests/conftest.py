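"""Shared fixtures: a hand-written two-gene annotation fixture plus
session-scoped simulated genomes/libraries reused across modules."""

import numpy as np
import pytest

from cas12akit import (GenomeModel, design_dual_library, read_genome,
                       simulate_genome)
from cas12akit.simulate import SimGenomeConfig


@pytest.fixture(scope="session")
def sim20():
    """Default 20-gene designable mini-genome (model, truth)."""
    return simulate_genome(SimGenomeConfig(n_genes=20, seed=1))


@pytest.fixture(scope="session")
def dual_lib20(sim20):
    model, _ = sim20
    return design_dual_library(model, n_ntc=20, seed=1)


def _rand_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


TWO_GENE_GFF = """##gff-version 3
chr1\ttest\tgene\t21\t200\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t21\t200\t.\t+\t.\tID=A_T1;Parent=geneA;tag=Ensembl_canonical
chr1\ttest\texon\t21\t80\t.\t+\t.\tParent=A_T1
chr1\ttest\texon\t121\t200\t.\t+\t.\tParent=A_T1
chr1\ttest\tCDS\t31\t80\t.\t+\t0\tParent=A_T1
chr1\ttest\tCDS\t121\t180\t.\t+\t0\tParent=A_T1
chr1\ttest\tmRNA\t21\t200\t.\t+\t.\tID=A_T2;Parent=geneA
chr1\ttest\texon\t21\t200\t.\t+\t.\tParent=A_T2
chr1\ttest\tCDS\t31\t90\t.\t+\t0\tParent=A_T2
chr1\ttest\tgene\t251\t350\t.\t-\t.\tID=geneB
chr1\ttest\tmRNA\t251\t350\t.\t-\t.\tID=B_T1;Parent=geneB
chr1\ttest\texon\t251\t350\t.\t-\t.\tParent=B_T1
chr1\ttest\tCDS\t261\t340\t.\t-\t0\tParent=B_T1
"""


@pytest.fixture(scope="session")
def two_gene_files(tmp_path_factory):
    """Hand-written FASTA + GFF3 pair; returns (fasta, gff, sequence)."""
    d = tmp_path_factory.mktemp("twogene")
    rng = np.random.default_rng(42)
    seq = _rand_dna(rng, 400)
    fasta = d / "g.fa"
    fasta.write_text(f">chr1\n{seq}\n")
    gff = d / "g.gff3"
    gff.write_text(TWO_GENE_GFF)
    return fasta, gff, seq


@pytest.fixture(scope="session")
def two_gene_model(two_gene_files):
    fasta, gff, _ = two_gene_files
    return read_genome(fasta, gff)


def make_bare_genome(contig_seq, ncrna=(), contig="c"):
    """GenomeModel with no genes, for constraint / NTC tests."""
    return GenomeModel(contigs={contig: contig_seq}, genes=[],
                       ncrna_intervals={(contig, s, e) for s, e in ncrna})
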