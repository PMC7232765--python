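import numpy as np
import pandas as pd
import pytest

from epifst import SimConfig, build_feature_model


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, fully featured simulation design for end-to-end tests."""
    return SimConfig(n_loci=200, n_tiles=150, n_genes=10,
                     genome_length=100_000, n_individuals_per_pop=12, seed=3)


TWO_GENE_GFF = """##gff-version 3
##sequence-region chr1 1 20000
chr1\ttest\tgene\t5001\t8000\t.\t+\t.\tID=gA
chr1\ttest\tmRNA\t5001\t8000\t.\t+\t.\tID=gA.t;Parent=gA
chr1\ttest\texon\t5001\t6000\t.\t+\t.\tID=gA.e1;Parent=gA.t
chr1\ttest\texon\t7001\t8000\t.\t+\t.\tID=gA.e2;Parent=gA.t
chr1\ttest\tfive_prime_UTR\t5001\t5200\t.\t+\t.\tID=gA.u5;Parent=gA.t
chr1\ttest\tthree_prime_UTR\t7801\t8000\t.\t+\t.\tID=gA.u3;Parent=gA.t
chr1\ttest\tgene\t14001\t16000\t.\t-\t.\tID=gB
chr1\ttest\tmRNA\t14001\t16000\t.\t-\t.\tID=gB.t;Parent=gB
chr1\ttest\texon\t14001\t16000\t.\t-\t.\tID=gB.e1;Parent=gB.t
"""


@pytest.fixture(scope="session")
def two_gene_model():
    """Plus-strand two-exon gene [5000,8000) and minus-strand single-exon
    gene [14000,16000) on a 20 kb chromosome."""
    return build_feature_model(TWO_GENE_GFF)
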