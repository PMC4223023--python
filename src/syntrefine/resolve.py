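"""Resolution of raw orthology links into syntenic one-to-one pairs.

Within each syntenic region the bipartite orthology graph is decomposed
into connected components (ortholog groups) and reduced to one-to-one
pairs in three steps: one-to-many groups keep the single highest-identity
partner; asymmetric many-to-many groups are trimmed to symmetry by
removing the genes with the lowest average identity to the rest of the
group; symmetric groups are split positionally, pairing the i-th gene of
one species with the i-th gene of the other in genomic order. Gene order,
not link identity, decides the final pairing of symmetric groups — the
goal is the positionally (syntenically) equivalent copy, and an emitted
pair need not correspond to an input link.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import Gene, OrthologGroup, OrthologyLink, ResolvedPair, SyntenicRegionPair

logger = logging.getLogger(__name__)

REMOVAL_REASONS = ("one_to_many_loser", "asymmetry_trim", "overlap_excluded", "no_ortholog")


@dataclass
class ResolutionReport:
    """Outcome of resolving one region: surviving pairs plus an account of
    every removed gene (id, reason) and the number of links dropped."""

    pairs: list = field(default_factory=list)
    removed_genes: list = field(default_factory=list)
    removed_links: int = 0

    def removed_ids(self, *reasons: str) -> set:
        return {gid for gid, reason in self.removed_genes if not reasons or reason in reasons}


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_orthologs(
    region_genes_A: Sequence[Gene],
    region_genes_B: Sequence[Gene],
    links: Sequence[OrthologyLink],
) -> list[OrthologGroup]:
    """Group a region's genes into connected components of the bipartite
    link graph.

    Only links with both endpoints among the given region genes are used.
    Genes with no link each form a singleton group of class ``no_ortholog``.
    Groups are returned in order of their first species-A gene (groups with
    no A-gene sort by their first B-gene after all A-anchored groups).
    """
    rank_A = {g.id: i for i, g in enumerate(region_genes_A)}
    rank_B = {g.id: i for i, g in enumerate(region_genes_B)}
    internal = [ln for ln in links if ln.gene_A in rank_A and ln.gene_B in rank_B]

    uf = _UnionFind()
    for ln in internal:
        uf.union(("A", ln.gene_A), ("B", ln.gene_B))

    comp_links: dict = {}
    for ln in internal:
        comp_links.setdefault(uf.find(("A", ln.gene_A)), []).append(ln)

    groups: list[OrthologGroup] = []
    for root, lns in comp_links.items():
        ga = sorted({ln.gene_A for ln in lns}, key=lambda g: rank_A[g])
        gb = sorted({ln.gene_B for ln in lns}, key=lambda g: rank_B[g])
        cls = "one_internal" if len(ga) == 1 and len(gb) == 1 else "many_internal"
        groups.append(
            OrthologGroup(
                genes_A=tuple(ga),
                genes_B=tuple(gb),
                links=tuple(sorted(lns, key=lambda ln: (rank_A[ln.gene_A], rank_B[ln.gene_B]))),
                cls=cls,
                rank_A={g: rank_A[g] for g in ga},
                rank_B={g: rank_B[g] for g in gb},
            )
        )

    linked_A = {ln.gene_A for ln in internal}
    linked_B = {ln.gene_B for ln in internal}
    for g in region_genes_A:
        if g.id not in linked_A:
            groups.append(
                OrthologGroup(genes_A=(g.id,), genes_B=(), links=(), cls="no_ortholog",
                              rank_A={g.id: rank_A[g.id]})
            )
    for g in region_genes_B:
        if g.id not in linked_B:
            groups.append(
                OrthologGroup(genes_A=(), genes_B=(g.id,), links=(), cls="no_ortholog",
                              rank_B={g.id: rank_B[g.id]})
            )

    def _key(gr: OrthologGroup) -> tuple:
        if gr.genes_A:
            return (0, gr.rank_A[gr.genes_A[0]])
        return (1, gr.rank_B[gr.genes_B[0]])

    groups.sort(key=_key)
    return groups


def _link_rank_distance(group: OrthologGroup, ln: OrthologyLink) -> int:
    ra = group.rank_A.get(ln.gene_A, 0)
    rb = group.rank_B.get(ln.gene_B, 0)
    return abs(ra - rb)


def reduce_one_to_many(group: OrthologGroup) -> tuple[ResolvedPair, list[str]]:
    """Reduce a one-to-many group to the single pair with the highest
    combined identity.

    Ties are broken by smaller genomic rank distance between the two genes
    within their regions, then lexicographic partner id. Returns the
    winning pair and the losing gene ids.
    """
    n, m = group.n, group.m
    if not ((n == 1 and m >= 2) or (m == 1 and n >= 2)):
        raise ValueError(
            f"reduce_one_to_many requires a 1-to-many group, got {n}x{m}"
        )
    best = min(
        group.links,
        key=lambda ln: (
            -ln.combined_identity,
            _link_rank_distance(group, ln),
            ln.gene_A,
            ln.gene_B,
        ),
    )
    pair = ResolvedPair(gene_A=best.gene_A, gene_B=best.gene_B,
                        provenance="one_to_many_reduced")
    losers = [g for g in group.genes_A if g != best.gene_A]
    losers += [g for g in group.genes_B if g != best.gene_B]
    return pair, losers


def _average_identity(group: OrthologGroup, gene: str, side: str) -> float:
    if side == "A":
        vals = [ln.combined_identity for ln in group.links if ln.gene_A == gene]
    else:
        vals = [ln.combined_identity for ln in group.links if ln.gene_B == gene]
    return sum(vals) / len(vals) if vals else 0.0


def symmetrize_group(group: OrthologGroup) -> tuple[OrthologGroup, list[str]]:
    """Trim an asymmetric many-to-many group to equal side sizes.

    Exactly ``|n - m|`` genes are removed from the larger side: those with
    the lowest average identity to their linked partners in the group
    (ascending ranking; ties broken by gene id). An already symmetric group
    is returned unchanged.
    """
    n, m = group.n, group.m
    if n == m:
        return group, []
    side = "A" if n > m else "B"
    delta = abs(n - m)
    members = group.genes_A if side == "A" else group.genes_B
    ranked = sorted(members, key=lambda g: (_average_identity(group, g, side), g))
    removed = ranked[:delta]
    removed_set = set(removed)
    if side == "A":
        keep_A = tuple(g for g in group.genes_A if g not in removed_set)
        keep_B = group.genes_B
    else:
        keep_A = group.genes_A
        keep_B = tuple(g for g in group.genes_B if g not in removed_set)
    keep_links = tuple(
        ln for ln in group.links
        if ln.gene_A not in removed_set and ln.gene_B not in removed_set
    )
    trimmed = OrthologGroup(
        genes_A=keep_A,
        genes_B=keep_B,
        links=keep_links,
        cls=group.cls,
        rank_A={g: group.rank_A[g] for g in keep_A},
        rank_B={g: group.rank_B[g] for g in keep_B},
    )
    return trimmed, removed


def split_symmetric_group(group: OrthologGroup) -> list[ResolvedPair]:
    """Split a symmetric group into one-to-one pairs by genomic order:
    the i-th A-gene (by position in the region) is paired with the i-th
    B-gene. The emitted pairs need not correspond to input links."""
    if group.n != group.m:
        raise ValueError(
            f"split_symmetric_group requires a symmetric group, got {group.n}x{group.m}"
        )
    ga = sorted(group.genes_A, key=lambda g: group.rank_A[g])
    gb = sorted(group.genes_B, key=lambda g: group.rank_B[g])
    if len(ga) == 1:
        return [ResolvedPair(gene_A=ga[0], gene_B=gb[0], provenance="direct")]
    return [
        ResolvedPair(gene_A=a, gene_B=b, provenance="order_split")
        for a, b in zip(ga, gb)
    ]


def find_overlapping_genes(genes: Sequence[Gene]) -> set:
    """Ids of genes whose coordinate interval overlaps another gene of the
    same (single-species) list on the same chromosome. All participants of
    an overlap are reported."""
    overlapping: set = set()
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.end, g.id))
        max_end = -1
        max_gene: Optional[Gene] = None
        for g in chrom_genes:
            if max_gene is not None and g.start < max_end:
                overlapping.add(g.id)
                overlapping.add(max_gene.id)
            if g.end > max_end:
                max_end, max_gene = g.end, g
    return overlapping


def resolve_region(
    region: SyntenicRegionPair,
    region_genes_A: Sequence[Gene],
    region_genes_B: Sequence[Gene],
    links: Sequence[OrthologyLink],
) -> ResolutionReport:
    """Run the full pre-processing for one region.

    Order of operations: same-species coordinate overlaps excluded first
    (all participants removed), then grouping, one-to-many reduction,
    symmetrization and order-based splitting. Every input gene ends up in
    exactly one ResolvedPair or in the removal report.
    """
    report = ResolutionReport()

    excluded = find_overlapping_genes(region_genes_A) | find_overlapping_genes(region_genes_B)
    for g in region_genes_A + list(region_genes_B):
        if g.id in excluded:
            report.removed_genes.append((g.id, "overlap_excluded"))
            logger.info("region %s: gene %s excluded (same-species overlap)",
                        region.region_id, g.id)
    genes_A = [g for g in region_genes_A if g.id not in excluded]
    genes_B = [g for g in region_genes_B if g.id not in excluded]

    ids_A = {g.id for g in region_genes_A}
    ids_B = {g.id for g in region_genes_B}
    region_links = [ln for ln in links if ln.gene_A in ids_A and ln.gene_B in ids_B]
    groups = group_orthologs(genes_A, genes_B, region_links)

    rank_A = {g.id: i for i, g in enumerate(genes_A)}
    pairs: list[ResolvedPair] = []
    for group in groups:
        if group.cls == "no_ortholog":
            gid = (group.genes_A or group.genes_B)[0]
            report.removed_genes.append((gid, "no_ortholog"))
            continue
        if group.n == 1 and group.m == 1:
            ln = group.links[0]
            pairs.append(ResolvedPair(gene_A=ln.gene_A, gene_B=ln.gene_B,
                                      provenance="direct"))
            continue
        if min(group.n, group.m) == 1:
            pair, losers = reduce_one_to_many(group)
            pairs.append(pair)
            for gid in losers:
                report.removed_genes.append((gid, "one_to_many_loser"))
                logger.info("region %s: gene %s removed (one-to-many loser)",
                            region.region_id, gid)
            continue
        group, trimmed = symmetrize_group(group)
        for gid in trimmed:
            report.removed_genes.append((gid, "asymmetry_trim"))
            logger.info("region %s: gene %s removed (asymmetry trim)",
                        region.region_id, gid)
        pairs.extend(split_symmetric_group(group))

    pairs.sort(key=lambda p: rank_A.get(p.gene_A, 0))
    report.pairs = pairs

    surviving = {p.gene_A for p in pairs} | {p.gene_B for p in pairs}
    report.removed_links = sum(
        1
        for ln in region_links
        if not (ln.gene_A in surviving and ln.gene_B in surviving)
    )
    return report
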