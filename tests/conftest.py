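"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crispri_art import guide_design, simulate
from crispri_art.genome_io import GeneFeature, GenomeRecord

# Hand-written two-gene GenBank fixture: geneA on + (1-based 10..39),
# geneB on - (complement(60..104)).
TWO_GENE_GENBANK = """\
LOCUS       testgenome               120 bp    DNA     linear   PHG 01-JAN-2025
DEFINITION  synthetic two-gene fixture.
ACCESSION   testgenome
VERSION     testgenome
FEATURES             Location/Qualifiers
     CDS             10..39
                     /locus_tag="geneA"
                     /product="protein A"
     CDS             complement(60..104)
                     /locus_tag="geneB"
                     /product="protein B"
ORIGIN
        1 acgtacgtaa tggcactgac catcagtgca gctaacgtta acgtacgtac gtacgtacgc
       61 tacatcgcat gacctgctag cgatcgtagc atcgcatatc gcgtacgtac gtacgtacgt
//
"""


@pytest.fixture
def two_gene_genbank(tmp_path):
    path = tmp_path / "two_gene.gb"
    path.write_text(TWO_GENE_GENBANK)
    return path


def make_single_gene_genome(upstream: int = 60, gene_len: int = 90,
                            downstream: int = 60, strand: str = "+",
                            seed: int = 11) -> tuple[GenomeRecord, GeneFeature]:
    """One gene with controlled flanking context, deterministic sequence."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=upstream + gene_len + downstream))
    feat = GeneFeature("gene1", upstream, upstream + gene_len, strand)
    return GenomeRecord("single", seq, "linear"), feat


@pytest.fixture
def ten_gene_genome():
    return simulate.simulate_genome(10, 10_000, seed=7)


@pytest.fixture
def rbs_library(ten_gene_genome):
    genome, features = ten_gene_genome
    guides = guide_design.design_rbs_panel(genome, features)
    return guide_design.guides_to_table(guides)


def random_spacer_library(n: int, length: int = 31, min_dist: int = 6,
                          seed: int = 0) -> pd.DataFrame:
    """Random spacers with enforced pairwise Hamming distance."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    spacers: list[str] = []
    while len(spacers) < n:
        cand = "".join(rng.choice(bases, size=length))
        if all(sum(a != b for a, b in zip(cand, s)) >= min_dist for s in spacers):
            spacers.append(cand)
    return pd.DataFrame({
        "guide_id": [f"rg{i:03d}" for i in range(n)],
        "gene_id": [f"rgene{i // 7:02d}" for i in range(n)],
        "spacer": spacers,
    })
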