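"""Breakpoint detection and block peeling within syntenic regions, plus
cross-region (external) translocation detection.

Model
-----
Within one region, the resolved one-to-one pairs are ordered by coordinate
in species A; ``pi[i]`` is the rank of pair *i*'s B-gene among the
region's B-genes. A *breakpoint* sits after position *i* whenever
``|pi[i+1] - pi[i]| != 1`` — the two A-neighbours are not neighbours in B.
Maximal breakpoint-free segments ("strips") are runs of pairs contiguous
in both species with consecutive, monotone ranks; they are the candidate
blocks and backbone pieces.

Peeling iterates to a fixpoint. The backbone must run in the region's
annotated orientation (ascending for "same"), so any multi-pair strip in
the opposite direction is an inversion block and is extracted outright —
this is what lets a whole-region inversion be recognised as a block even
when it covers the majority of genes. Among co-oriented strips, each
breakpoint proposes the shorter of its two flanking segments (segments
being delimited by the adjacent breakpoints or the region ends) and the
globally smallest proposal is extracted as a translocation block; ranks
are then recomputed and the process repeats until no breakpoints remain.
The global choice keeps the procedure symmetric under swapping the
reference genome: the same translocated segment is found whichever
species plays the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import RegionAssignment, assign_genes_to_regions
from .model import (
    Gene,
    GenomePairDataset,
    OrthologyLink,
    RefinedRegion,
    ResolvedPair,
    SyntenicRegionPair,
    region_sort_key,
)
from .resolve import ResolutionReport, resolve_region

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ranked regions and breakpoints
# ---------------------------------------------------------------------------


@dataclass
class RankedRegion:
    """A region's resolved pairs in A-coordinate order with B-rank
    permutation ``pi`` (1-based ranks) and per-pair strand information."""

    region_id: str
    pairs: tuple
    pi: tuple
    genes_A: tuple
    genes_B: tuple

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def strands(self) -> tuple:
        return tuple((a.strand, b.strand) for a, b in zip(self.genes_A, self.genes_B))


@dataclass(frozen=True)
class Breakpoint:
    """Unconserved neighbourhood after A-position ``after_index`` (1-based):
    pairs ``after_index`` and ``after_index + 1`` are adjacent in A but
    their B-genes are not adjacent in B."""

    region_id: str
    after_index: int
    b_indices: tuple


@dataclass
class Block:
    """A peeled micro-rearranged block.

    ``member_indices`` are positions into the parent RankedRegion's pairs
    (contiguous in A among the pairs surviving at extraction time);
    ``ranks_at_extraction`` are the collapsed B-ranks at that moment — a
    consecutive monotone run. ``direction`` is +1 (order preserved), -1
    (order reversed) or 0 (single pair)."""

    region_id: str
    member_indices: tuple
    kind: Optional[str] = None
    nesting_parent: Optional[int] = None
    direction: int = 0
    ranks_at_extraction: tuple = ()


def _collapse_ranks(values: Sequence) -> list[int]:
    """Map distinct values to their 1..m rank order."""
    order = sorted(range(len(values)), key=values.__getitem__)
    ranks = [0] * len(values)
    for r, idx in enumerate(order, start=1):
        ranks[idx] = r
    return ranks


def rank_region(pairs: Sequence[ResolvedPair], genes_by_id: dict,
                region_id: str = "") -> RankedRegion:
    """Order a region's pairs by A-coordinate and compute the B-rank
    permutation. Genes without resolved orthologs are invisible here."""
    if not pairs:
        return RankedRegion(region_id=region_id, pairs=(), pi=(), genes_A=(), genes_B=())
    ga = [genes_by_id[p.gene_A] for p in pairs]
    gb = [genes_by_id[p.gene_B] for p in pairs]
    a_order = sorted(range(len(pairs)),
                     key=lambda i: (ga[i].start, ga[i].end, ga[i].id))
    pairs = tuple(pairs[i] for i in a_order)
    ga = [ga[i] for i in a_order]
    gb = [gb[i] for i in a_order]
    pi = _collapse_ranks([(g.start, g.end, g.id) for g in gb])
    return RankedRegion(region_id=region_id, pairs=pairs, pi=tuple(pi),
                        genes_A=tuple(ga), genes_B=tuple(gb))


def find_breakpoints(r: RankedRegion) -> list[Breakpoint]:
    """All positions where B-adjacency of two A-adjacent pairs is broken."""
    out = []
    for i in range(len(r.pi) - 1):
        if abs(r.pi[i + 1] - r.pi[i]) != 1:
            out.append(Breakpoint(region_id=r.region_id, after_index=i + 1,
                                  b_indices=(r.pi[i], r.pi[i + 1])))
    return out


# ---------------------------------------------------------------------------
# strips and peeling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Strip:
    start: int  # position slice [start, end) into the current work list
    end: int
    direction: int  # +1 ascending, -1 descending, 0 single

    @property
    def size(self) -> int:
        return self.end - self.start


def strip_decomposition(ranks: Sequence[int]) -> list[_Strip]:
    """Maximal runs of consecutive monotone ranks (breakpoint-free
    segments). A strip is contiguous in both species by construction."""
    n = len(ranks)
    strips: list[_Strip] = []
    i = 0
    while i < n:
        j = i + 1
        direction = 0
        while j < n:
            d = ranks[j] - ranks[j - 1]
            if d in (1, -1) and (direction == 0 or d == direction):
                direction = d
                j += 1
            else:
                break
        strips.append(_Strip(start=i, end=j, direction=direction if j - i > 1 else 0))
        i = j
    return strips


def peel_permutation(
    pi: Sequence[int],
    spans: Optional[Sequence[int]] = None,
    expected_direction: int = 1,
):
    """Core peeling on a bare permutation.

    ``pi`` holds distinct integers (B-ranks in A-order); ``spans`` gives
    optional per-pair A-extents in bp for tie-breaking. Returns
    ``(backbone_positions, blocks)`` where each block is a tuple
    ``(member_positions, direction, ranks_at_extraction)`` and positions
    index into the original ``pi``.
    """
    work = list(range(len(pi)))
    blocks = []

    def _span(strip: _Strip, current: list) -> int:
        if spans is None:
            return 0
        return sum(spans[current[j]] for j in range(strip.start, strip.end))

    while work:
        ranks = _collapse_ranks([pi[p] for p in work])
        strips = strip_decomposition(ranks)

        counters = [s for s in strips if s.size > 1 and s.direction == -expected_direction]
        if counters:
            chosen = min(counters, key=lambda s: (s.size, _span(s, work), s.start))
        else:
            if len(strips) <= 1:
                break
            proposals = []
            for k in range(len(strips) - 1):
                left, right = strips[k], strips[k + 1]
                if left.size != right.size:
                    cand = left if left.size < right.size else right
                else:
                    sl, sr = _span(left, work), _span(right, work)
                    # tie: fewer spanned bp in A, then the downstream segment
                    cand = left if sl < sr else right
                proposals.append(cand)
            chosen = min(proposals, key=lambda s: (s.size, _span(s, work), s.start))

        members = tuple(work[j] for j in range(chosen.start, chosen.end))
        ranks_at = tuple(ranks[chosen.start:chosen.end])
        blocks.append((members, chosen.direction, ranks_at))
        del work[chosen.start:chosen.end]

    return work, blocks


def _dominant_strand_relation(r: RankedRegion, indices: Sequence[int],
                              expected_direction: int) -> bool:
    """Majority value of (strand_A == strand_B) over the given pairs;
    falls back to the region orientation's expectation when empty or tied."""
    same = sum(1 for i in indices if r.genes_A[i].strand == r.genes_B[i].strand)
    diff = len(list(indices)) - same
    if same != diff:
        return same > diff
    return expected_direction == 1


def classify_block(b: Block, r: RankedRegion,
                   backbone_indices: Optional[Sequence[int]] = None,
                   expected_direction: int = 1) -> str:
    """Classify a block as translocation (order preserved) or inversion
    (order reversed).

    Multi-pair blocks are classified by gene order; if gene strands
    disagree with the order-based call, order wins and the conflict is
    logged. A single-pair block is an inversion iff its strand relation
    differs from the backbone's dominant strand relation.
    """
    idx = list(b.member_indices)
    if len(idx) > 1:
        descending = all(r.pi[i] > r.pi[j] for i, j in zip(idx, idx[1:]))
        kind = "inversion" if descending else "translocation"
        if backbone_indices is not None:
            dominant = _dominant_strand_relation(r, backbone_indices, expected_direction)
            relation = _dominant_strand_relation(r, idx, expected_direction)
            strand_kind = "inversion" if relation != dominant else "translocation"
            if strand_kind != kind:
                logger.info(
                    "region %s: strand/order disagreement for block at %s; order wins (%s)",
                    r.region_id, idx, kind,
                )
        return kind
    i = idx[0]
    relation = r.genes_A[i].strand == r.genes_B[i].strand
    if backbone_indices is None:
        backbone_indices = [j for j in range(len(r)) if j != i]
    dominant = _dominant_strand_relation(r, backbone_indices, expected_direction)
    return "inversion" if relation != dominant else "translocation"


def peel_blocks(r: RankedRegion, orientation: Optional[str] = None):
    """Peel all micro-rearranged blocks out of a ranked region.

    Returns ``(backbone, blocks)``: the backbone as a new RankedRegion
    whose permutation is strictly monotone (re-running breakpoint
    detection on it finds nothing), and the extracted blocks with kinds
    assigned and nesting parents resolved by A-coordinate containment.
    """
    expected = -1 if orientation == "opposite" else 1
    if len(r) <= 1:
        return r, []

    spans = [g.length for g in r.genes_A]
    backbone_pos, raw_blocks = peel_permutation(r.pi, spans=spans,
                                                expected_direction=expected)

    blocks: list[Block] = []
    for members, direction, ranks_at in raw_blocks:
        blocks.append(Block(region_id=r.region_id, member_indices=members,
                            direction=direction, ranks_at_extraction=ranks_at))
    for b in blocks:
        b.kind = classify_block(b, r, backbone_indices=backbone_pos,
                                expected_direction=expected)

    # nesting: smallest other block whose A-span strictly contains this one
    def _a_span(indices):
        return (min(r.genes_A[i].start for i in indices),
                max(r.genes_A[i].end for i in indices))

    span_of = [_a_span(b.member_indices) for b in blocks]
    for i, b in enumerate(blocks):
        s, e = span_of[i]
        best = None
        for j, other in enumerate(blocks):
            if i == j:
                continue
            os, oe = span_of[j]
            if os <= s and e <= oe and (os, oe) != (s, e):
                if best is None or (span_of[best][1] - span_of[best][0]) > (oe - os):
                    best = j
        b.nesting_parent = best

    backbone_pairs = tuple(r.pairs[i] for i in backbone_pos)
    backbone = RankedRegion(
        region_id=r.region_id,
        pairs=backbone_pairs,
        pi=tuple(_collapse_ranks([r.pi[i] for i in backbone_pos])),
        genes_A=tuple(r.genes_A[i] for i in backbone_pos),
        genes_B=tuple(r.genes_B[i] for i in backbone_pos),
    )
    return backbone, blocks


# ---------------------------------------------------------------------------
# external translocations
# ---------------------------------------------------------------------------


@dataclass
class ExternalRun:
    """A maximal run of consecutive external ortholog pairs joining the
    same two regions with consistent order. ``source_region`` holds the
    A-genes, ``target_region`` the B-genes."""

    source_region: str
    target_region: str
    pairs: tuple
    direction: int = 1


def detect_external_blocks(
    assignment: RegionAssignment,
    reports: dict,
    links: Sequence[OrthologyLink],
    genes_by_id: dict,
) -> list[ExternalRun]:
    """Pair genes that have no ortholog within their own region with
    internally-unpaired partners in other regions, then merge consecutive
    consistent pairs into runs.

    Both endpoints must be internally unpaired; a gene eligible for
    several external partners takes the highest combined identity (logged).
    """
    region_of: dict = {}
    for rid, (ga, gb) in assignment.by_region.items():
        for g in ga:
            region_of[g.id] = rid
        for g in gb:
            region_of[g.id] = rid

    paired: set = set()
    overlap_excluded: set = set()
    for rep in reports.values():
        for p in rep.pairs:
            paired.add(p.gene_A)
            paired.add(p.gene_B)
        overlap_excluded |= rep.removed_ids("overlap_excluded")

    has_internal_link: set = set()
    for ln in links:
        ra, rb = region_of.get(ln.gene_A), region_of.get(ln.gene_B)
        if ra is not None and ra == rb:
            has_internal_link.add(ln.gene_A)
            has_internal_link.add(ln.gene_B)

    def eligible(gid: str) -> bool:
        return (
            gid in region_of
            and gid not in paired
            and gid not in overlap_excluded
            and gid not in has_internal_link
        )

    candidates = [
        ln for ln in links
        if eligible(ln.gene_A) and eligible(ln.gene_B)
        and region_of[ln.gene_A] != region_of[ln.gene_B]
    ]
    n_options: dict = {}
    for ln in candidates:
        n_options[ln.gene_A] = n_options.get(ln.gene_A, 0) + 1
        n_options[ln.gene_B] = n_options.get(ln.gene_B, 0) + 1
    candidates.sort(key=lambda ln: (-ln.combined_identity, ln.gene_A, ln.gene_B))

    used: set = set()
    chosen = []
    for ln in candidates:
        if ln.gene_A in used or ln.gene_B in used:
            continue
        if n_options.get(ln.gene_A, 0) > 1 or n_options.get(ln.gene_B, 0) > 1:
            logger.info(
                "external pairing: %s-%s chosen by highest identity among "
                "multiple eligible partners", ln.gene_A, ln.gene_B,
            )
        used.add(ln.gene_A)
        used.add(ln.gene_B)
        chosen.append(ln)

    order_index: dict = {}
    for rid, (ga, gb) in assignment.by_region.items():
        for i, g in enumerate(ga):
            order_index[g.id] = i
        for i, g in enumerate(gb):
            order_index[g.id] = i

    annotated = sorted(
        (
            (region_of[ln.gene_A], order_index[ln.gene_A],
             region_of[ln.gene_B], order_index[ln.gene_B], ln)
            for ln in chosen
        ),
        key=lambda t: (region_sort_key(t[0]), t[1]),
    )

    runs: list[ExternalRun] = []
    current: list = []
    cur_dir = 0
    for entry in annotated:
        if current:
            prev = current[-1]
            same_join = entry[0] == prev[0] and entry[2] == prev[2]
            a_adjacent = entry[1] == prev[1] + 1
            step = entry[3] - prev[3]
            b_consistent = step in (1, -1) and (cur_dir == 0 or step == cur_dir)
            if same_join and a_adjacent and b_consistent:
                cur_dir = step
                current.append(entry)
                continue
            runs.append(_finish_run(current, cur_dir))
            current, cur_dir = [], 0
        current.append(entry)
    if current:
        runs.append(_finish_run(current, cur_dir))
    return runs


def _finish_run(entries: list, direction: int) -> ExternalRun:
    pairs = tuple(
        ResolvedPair(gene_A=e[4].gene_A, gene_B=e[4].gene_B, provenance="external")
        for e in entries
    )
    return ExternalRun(
        source_region=entries[0][0],
        target_region=entries[0][2],
        pairs=pairs,
        direction=direction if direction else 1,
    )


# ---------------------------------------------------------------------------
# whole-dataset refinement
# ---------------------------------------------------------------------------


@dataclass
class RefinementResult:
    refined: list
    reports: dict
    assignment: RegionAssignment
    ranked: dict
    backbones: dict
    blocks: dict
    external_runs: list

    def summary(self) -> dict:
        counts = {"original": 0, "internal": 0, "external": 0,
                  "translocation": 0, "inversion": 0, "pairs": 0}
        for r in self.refined:
            counts[r.type] += 1
            if r.rearrangement != "none":
                counts[r.rearrangement] += 1
            counts["pairs"] += len(r.member_pairs)
        removals: dict = {}
        for rep in self.reports.values():
            for _, reason in rep.removed_genes:
                removals[reason] = removals.get(reason, 0) + 1
        counts["removed"] = removals
        counts["unassigned_genes"] = len(self.assignment.unassigned)
        return counts


def _gene_span(genes: Sequence[Gene]):
    return (genes[0].chromosome,
            min(g.start for g in genes),
            max(g.end for g in genes))


def refine_all(dataset: GenomePairDataset) -> RefinementResult:
    """Run the complete pipeline: assignment, per-region resolution,
    peeling, external detection, and refined-region construction.

    Every input region yields one "original" region (its collinear
    backbone, keeping the input coordinates) plus one "internal" region
    per peeled block and "external" regions for cross-region runs.
    Derived regions are numbered ``<parent>_<k>`` in A-coordinate order
    and span their member genes in each species.
    """
    genes_by_id = {g.id: g for g in dataset.genes_A}
    genes_by_id.update({g.id: g for g in dataset.genes_B})
    assignment = assign_genes_to_regions(
        list(dataset.genes_A) + list(dataset.genes_B), dataset.regions
    )
    for g in assignment.unassigned:
        logger.debug("gene %s lies in no syntenic region (syntenic-block-free)", g.id)

    reports: dict = {}
    ranked: dict = {}
    backbones: dict = {}
    blocks: dict = {}
    region_by_id = {r.region_id: r for r in dataset.regions}

    # bucket links by region so each region only scans its own links
    region_of_gene: dict = {}
    for rid, (ga, gb) in assignment.by_region.items():
        for g in ga:
            region_of_gene[g.id] = rid
        for g in gb:
            region_of_gene[g.id] = rid
    link_bucket: dict = {rid: [] for rid in region_by_id}
    for ln in dataset.links:
        ra = region_of_gene.get(ln.gene_A)
        if ra is not None and region_of_gene.get(ln.gene_B) == ra:
            link_bucket[ra].append(ln)

    for region in dataset.regions:
        ga, gb = assignment.by_region[region.region_id]
        rep = resolve_region(region, ga, gb, link_bucket[region.region_id])
        reports[region.region_id] = rep
        rr = rank_region(rep.pairs, genes_by_id, region_id=region.region_id)
        ranked[region.region_id] = rr
        backbone, blks = peel_blocks(rr, orientation=region.orientation)
        backbones[region.region_id] = backbone
        blocks[region.region_id] = blks

    external_runs = detect_external_blocks(assignment, reports, dataset.links,
                                           genes_by_id)

    children: dict = {rid: [] for rid in region_by_id}
    for rid, blks in blocks.items():
        rr = ranked[rid]
        for b in blks:
            ga = [rr.genes_A[i] for i in b.member_indices]
            gb = [rr.genes_B[i] for i in b.member_indices]
            children[rid].append(("internal", b.kind, ga, gb,
                                  tuple(rr.pairs[i] for i in b.member_indices), None))
    for run in external_runs:
        ga = [genes_by_id[p.gene_A] for p in run.pairs]
        gb = [genes_by_id[p.gene_B] for p in run.pairs]
        children[run.source_region].append(
            ("external", "translocation", ga, gb, run.pairs, run.target_region)
        )

    refined: list[RefinedRegion] = []
    for region in dataset.regions:
        rid = region.region_id
        backbone = backbones[rid]
        refined.append(
            RefinedRegion(
                region_id=rid,
                parent_region_id=None,
                type="original",
                rearrangement="none",
                chrom_A=region.chrom_A, start_A=region.start_A, end_A=region.end_A,
                chrom_B=region.chrom_B, start_B=region.start_B, end_B=region.end_B,
                member_pairs=tuple(backbone.pairs),
            )
        )
        kids = sorted(children[rid], key=lambda c: min(g.start for g in c[2]))
        for counter, (rtype, kind, ga, gb, pairs, _target) in enumerate(kids, start=1):
            chrom_a, start_a, end_a = _gene_span(ga)
            chrom_b, start_b, end_b = _gene_span(gb)
            refined.append(
                RefinedRegion(
                    region_id=f"{rid}_{counter}",
                    parent_region_id=rid,
                    type=rtype,
                    rearrangement=kind,
                    chrom_A=chrom_a, start_A=start_a, end_A=end_a,
                    chrom_B=chrom_b, start_B=start_b, end_B=end_b,
                    member_pairs=tuple(pairs),
                )
            )

    refined.sort(key=lambda r: (region_sort_key(r.region_id), r.start_A))
    return RefinementResult(
        refined=refined,
        reports=reports,
        assignment=assignment,
        ranked=ranked,
        backbones=backbones,
        blocks=blocks,
        external_runs=external_runs,
    )
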