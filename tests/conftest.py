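"""Shared builders for hand-crafted regions and datasets."""

from __future__ import annotations

import pytest

from syntrefine.model import (
    Gene,
    GenomePairDataset,
    OrthologyLink,
    ResolvedPair,
    SyntenicRegionPair,
)
from syntrefine.rearrange import rank_region


def make_gene(gid, species, start, end=None, chrom=None, strand="+"):
    if chrom is None:
        chrom = f"chr{species}1"
    if end is None:
        end = start + 1_000
    return Gene(id=gid, species=species, chromosome=chrom, start=start, end=end,
                strand=strand)


def region_from_permutation(pi, strands=None, region_id="r", gene_bp=1_000):
    """Build a RankedRegion whose B-rank permutation equals ``pi``.

    ``pi`` is a sequence of distinct integers; pair i (in A order) gets a
    B-gene placed at rank pi[i]. ``strands`` optionally gives per-pair
    (strand_A, strand_B) tuples.
    """
    n = len(pi)
    if strands is None:
        strands = [("+", "+")] * n
    genes = {}
    pairs = []
    for i in range(n):
        a = make_gene(f"a{i}", "A", start=10_000 * (i + 1),
                      end=10_000 * (i + 1) + gene_bp, strand=strands[i][0])
        b = make_gene(f"b{i}", "B", start=10_000 * pi[i],
                      end=10_000 * pi[i] + gene_bp, strand=strands[i][1])
        genes[a.id] = a
        genes[b.id] = b
        pairs.append(ResolvedPair(gene_A=a.id, gene_B=b.id))
    return rank_region(pairs, genes, region_id=region_id), genes


def tiny_two_region_dataset():
    """Two regions with a cross-region orphan ortholog pair: region 1 gene
    a_x has its only ortholog b_y in region 2 and vice versa."""
    genes_A, genes_B, links = [], [], []
    for r, base in (("1", 100_000), ("2", 900_000)):
        for i in range(4):
            a = make_gene(f"a{r}_{i}", "A", base + 20_000 * i)
            b = make_gene(f"b{r}_{i}", "B", base + 20_000 * i)
            genes_A.append(a)
            genes_B.append(b)
            links.append(OrthologyLink(gene_A=a.id, gene_B=b.id,
                                       identity_AB=90.0, identity_BA=90.0))
    # orphans: a1_x in region 1 <-> b2_x in region 2
    a_x = make_gene("a1_x", "A", 100_000 + 20_000 * 4)
    b_x = make_gene("b2_x", "B", 900_000 + 20_000 * 4)
    genes_A.append(a_x)
    genes_B.append(b_x)
    links.append(OrthologyLink(gene_A=a_x.id, gene_B=b_x.id,
                               identity_AB=85.0, identity_BA=85.0))
    regions = [
        SyntenicRegionPair(region_id="1",
                           chrom_A="chrA1", start_A=90_000, end_A=250_000,
                           chrom_B="chrB1", start_B=90_000, end_B=250_000),
        SyntenicRegionPair(region_id="2",
                           chrom_A="chrA1", start_A=890_000, end_A=1_050_000,
                           chrom_B="chrB1", start_B=890_000, end_B=1_050_000),
    ]
    return GenomePairDataset(genes_A=genes_A, genes_B=genes_B,
                             regions=regions, links=links)


@pytest.fixture
def two_region_dataset():
    return tiny_two_region_dataset()
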