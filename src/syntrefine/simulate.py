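"""Seedable synthetic genome pairs with planted micro-rearrangements.

The generator lays out two collinear genomes (one chromosome per
species, regions in the same order, every gene with exactly one
ortholog) and then plants ground-truth events by rewriting the gene
order of species B:

* internal translocations relocate a run of genes within its region,
* inversions reverse a run in place (strands flipped),
* external translocations move a run of B-genes into another region,
* duplications add extra linked gene copies with controlled identity
  ranking, so the intended resolution loser is known.

Planted geometry respects the detector's preconditions: every planted
run surfaces as exactly one breakpoint-free segment and every backbone
segment is strictly longer than every planted translocation run in its
region (the shorter-segment rule then attributes blocks, not backbone).
Gene lengths are drawn log-normally around 45-60 kb, echoing mammalian
protein-coding gene scales; the layout is cosmetic and does not affect
detection, which only sees order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import assign_genes_to_regions
from .model import (
    FeatureTrack,
    Gene,
    GenomePairDataset,
    OrthologyLink,
    SyntenicRegionPair,
)
from .rearrange import RefinementResult, strip_decomposition, _collapse_ranks


class CapacityError(ValueError):
    """Requested events do not fit the dataset's capacity."""


@dataclass(frozen=True)
class PlantedEvent:
    kind: str  # internal_translocation | inversion | external_translocation
    pairs: tuple  # ((gene_A, gene_B), ...) in A order
    region_id: str
    target_region_id: Optional[str] = None


@dataclass
class PlantedTruth:
    events: tuple = ()
    intended_losers: tuple = ()


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

_MARGIN = 5_000
_INTER_REGION = 200_000


def _layout_species(
    rng: np.random.Generator,
    region_ids: Sequence[str],
    orders: dict,
    lengths: dict,
    strands: dict,
    species: str,
    chrom: str,
):
    """Place regions sequentially along one chromosome; returns
    (genes, {region_id: (start, end)})."""
    genes: list[Gene] = []
    intervals: dict = {}
    pos = 100_000
    for rid in region_ids:
        pos += _INTER_REGION
        region_start = pos
        last_end = region_start + 1
        pos += _MARGIN
        for gid in orders[rid]:
            start = pos
            end = start + lengths[gid]
            genes.append(Gene(id=gid, species=species, chromosome=chrom,
                              start=start, end=end, strand=strands[gid]))
            last_end = end
            pos = end + int(rng.integers(5_000, 50_000))
        intervals[rid] = (region_start, last_end + _MARGIN)
        pos = last_end + _MARGIN
    return genes, intervals


def _draw_length(rng: np.random.Generator, median: float) -> int:
    return max(200, int(rng.lognormal(mean=np.log(median), sigma=0.35)))


def generate_genome_pair(
    n_regions: int, genes_per_region: int, seed
) -> tuple[GenomePairDataset, PlantedTruth]:
    """A fully collinear genome pair: species B mirrors species A region
    by region and gene by gene, with one orthology link per gene whose
    percent identities are drawn in [60, 100]."""
    if n_regions < 1 or genes_per_region < 2:
        raise ValueError("need n_regions >= 1 and genes_per_region >= 2")
    rng = np.random.default_rng(seed)
    region_ids = [str(r + 1) for r in range(n_regions)]

    orders_A: dict = {}
    orders_B: dict = {}
    lengths: dict = {}
    strands: dict = {}
    links: list[OrthologyLink] = []
    for rid in region_ids:
        a_ids, b_ids = [], []
        for i in range(genes_per_region):
            aid = f"gA_r{rid}_{i:03d}"
            bid = f"gB_r{rid}_{i:03d}"
            a_ids.append(aid)
            b_ids.append(bid)
            lengths[aid] = _draw_length(rng, 55_000)
            lengths[bid] = _draw_length(rng, 45_000)
            strand = "+" if rng.random() < 0.5 else "-"
            strands[aid] = strand
            strands[bid] = strand
            ident = float(rng.uniform(60.0, 100.0))
            back = float(np.clip(ident + rng.normal(0.0, 1.5), 0.0, 100.0))
            links.append(OrthologyLink(gene_A=aid, gene_B=bid,
                                       identity_AB=round(ident, 3),
                                       identity_BA=round(back, 3)))
        orders_A[rid] = a_ids
        orders_B[rid] = b_ids

    genes_A, iv_A = _layout_species(rng, region_ids, orders_A, lengths, strands,
                                    "A", "chrA1")
    genes_B, iv_B = _layout_species(rng, region_ids, orders_B, lengths, strands,
                                    "B", "chrB1")
    regions = [
        SyntenicRegionPair(
            region_id=rid,
            chrom_A="chrA1", start_A=iv_A[rid][0], end_A=iv_A[rid][1],
            chrom_B="chrB1", start_B=iv_B[rid][0], end_B=iv_B[rid][1],
            orientation="same",
        )
        for rid in region_ids
    ]
    dataset = GenomePairDataset(genes_A=genes_A, genes_B=genes_B,
                                regions=regions, links=links)
    return dataset, PlantedTruth()


def chromosome_sizes(dataset: GenomePairDataset, margin: int = 100_000) -> dict:
    sizes: dict = {}
    for g in list(dataset.genes_A) + list(dataset.genes_B):
        sizes[g.chromosome] = max(sizes.get(g.chromosome, 0), g.end + margin)
    return sizes


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def _partner_map(dataset: GenomePairDataset) -> dict:
    partners: dict = {}
    for ln in dataset.links:
        if ln.gene_A in partners:
            raise ValueError("plant_rearrangements requires a one-to-one dataset")
        partners[ln.gene_A] = ln.gene_B
    return partners


def plant_rearrangements(
    dataset: GenomePairDataset,
    n_internal: int,
    n_external: int,
    max_block_genes: int = 5,
    p_inversion: float = 0.5,
    p_duplication: float = 0.0,
    seed=None,
    external_run_genes: Optional[int] = None,
) -> tuple[GenomePairDataset, PlantedTruth]:
    """Plant rearrangements and duplications into a collinear dataset.

    Returns a new dataset (species B rewritten and re-laid-out) plus the
    planted ground truth. Raises :class:`CapacityError` when the
    requested events cannot be placed disjointly while keeping every
    backbone segment strictly longer than every planted translocation.
    """
    rng = np.random.default_rng(seed)
    partners = _partner_map(dataset)
    assignment = assign_genes_to_regions(
        list(dataset.genes_A) + list(dataset.genes_B), dataset.regions
    )
    region_ids = [r.region_id for r in dataset.regions]
    a_order = {rid: [g.id for g in assignment.by_region[rid][0]] for rid in region_ids}
    for rid in region_ids:
        b_sorted = [g.id for g in assignment.by_region[rid][1]]
        if b_sorted != [partners[a] for a in a_order[rid]]:
            raise ValueError("plant_rearrangements requires an unrearranged dataset")
    if n_external and len(region_ids) < 2:
        raise CapacityError("external events need at least two regions")

    last_error: Optional[CapacityError] = None
    for _outer in range(20):
        try:
            plans = _plan_all(rng, region_ids, a_order, n_internal, n_external,
                              max_block_genes, p_inversion, external_run_genes)
            orders, flipped, events, moved_out = _build_orders(
                rng, region_ids, a_order, partners, *plans
            )
            internal_plans = plans[1]
            for rid in region_ids:
                _validate_region(rid, a_order[rid], orders[rid], partners,
                                 internal_plans[rid], moved_out[rid])
            break
        except CapacityError as exc:
            last_error = exc
    else:
        raise CapacityError(f"could not place requested events: {last_error}")

    # ---- plan duplications -------------------------------------------------
    event_genes: dict = {rid: set() for rid in region_ids}
    for ev in events:
        src = ev.region_id
        for aid, _bid in ev.pairs:
            event_genes[src].add(aid)
    dup_specs = []  # (kind, rid, A-order indices)
    for rid in region_ids:
        G = len(a_order[rid])
        i = 0
        while i < G:
            if a_order[rid][i] in event_genes[rid] or rng.random() >= p_duplication:
                i += 1
                continue
            if (rng.random() < 0.4 and i + 1 < G
                    and a_order[rid][i + 1] not in event_genes[rid]):
                dup_specs.append(("many_to_many", rid, (i, i + 1)))
                i += 2
            else:
                dup_specs.append(("one_to_many", rid, (i,)))
                i += 1

    # ---- duplications ------------------------------------------------------
    losers: list[str] = []
    extra_lengths: dict = {}
    extra_strands: dict = {}
    new_links = list(dataset.links)
    link_by_a = {ln.gene_A: ln for ln in dataset.links}
    for kind, rid, idxs in dup_specs:
        order = orders[rid]
        if kind == "one_to_many":
            aid = a_order[rid][idxs[0]]
            bid = partners[aid]
            dup = f"{bid}_dup"
            base = link_by_a[aid]
            low = max(0.0, base.combined_identity - float(rng.uniform(8.0, 20.0)))
            new_links.append(OrthologyLink(gene_A=aid, gene_B=dup,
                                           identity_AB=round(low, 3),
                                           identity_BA=round(low, 3)))
            order.insert(order.index(bid) + 1, dup)
            extra_lengths[dup] = _draw_length(rng, 45_000)
            extra_strands[dup] = "+" if rng.random() < 0.5 else "-"
            losers.append(dup)
        else:
            a1, a2 = (a_order[rid][i] for i in idxs)
            b1, b2 = partners[a1], partners[a2]
            hi = min(link_by_a[a1].combined_identity, link_by_a[a2].combined_identity)
            cross = max(0.0, hi - float(rng.uniform(5.0, 10.0)))
            dup = f"{b2}_dup"
            lowest = max(0.0, cross - float(rng.uniform(8.0, 15.0)))
            new_links.append(OrthologyLink(gene_A=a1, gene_B=b2,
                                           identity_AB=round(cross, 3),
                                           identity_BA=round(cross, 3)))
            new_links.append(OrthologyLink(gene_A=a2, gene_B=dup,
                                           identity_AB=round(lowest, 3),
                                           identity_BA=round(lowest, 3)))
            order.insert(order.index(b2) + 1, dup)
            extra_lengths[dup] = _draw_length(rng, 45_000)
            extra_strands[dup] = "+" if rng.random() < 0.5 else "-"
            losers.append(dup)

    # ---- re-lay-out species B ---------------------------------------------
    length_of = {g.id: g.length for g in dataset.genes_B}
    length_of.update(extra_lengths)
    strand_of = {g.id: g.strand for g in dataset.genes_B}
    strand_of.update(extra_strands)
    for bid in flipped:
        strand_of[bid] = "-" if strand_of[bid] == "+" else "+"

    b_region_order = sorted(region_ids,
                            key=lambda rid: dict(
                                (r.region_id, r.start_B) for r in dataset.regions
                            )[rid])
    chrom_B = dataset.regions[0].chrom_B
    genes_B, iv_B = _layout_species(rng, b_region_order, orders, length_of,
                                    strand_of, "B", chrom_B)
    iv = {rid: iv_B[rid] for rid in region_ids}
    regions = [
        replace(r, start_B=iv[r.region_id][0], end_B=iv[r.region_id][1])
        for r in dataset.regions
    ]

    new_dataset = GenomePairDataset(
        genes_A=list(dataset.genes_A),
        genes_B=genes_B,
        regions=regions,
        links=new_links,
    )
    return new_dataset, PlantedTruth(events=tuple(events),
                                     intended_losers=tuple(losers))


def _plan_all(rng, region_ids, a_order, n_internal, n_external,
              max_block_genes, p_inversion, external_run_genes):
    """One attempt at planning every event; raises CapacityError on any
    placement failure so the caller can retry or give up."""
    external_plans = []  # (src_rid, start, length, tgt_rid)
    ext_blocked: dict = {rid: set() for rid in region_ids}
    for _ in range(n_external):
        for _attempt in range(200):
            src = region_ids[int(rng.integers(0, len(region_ids)))]
            G = len(a_order[src])
            if external_run_genes is not None:
                L = int(external_run_genes)
            else:
                L = 1 if rng.random() < 0.8 else 2
            if L >= G:
                continue
            s = int(rng.integers(0, G - L + 1))
            if any(i in ext_blocked[src] for i in range(s, s + L)):
                continue
            tgt = region_ids[int(rng.integers(0, len(region_ids)))]
            if tgt == src:
                continue
            ext_blocked[src].update(range(s, s + L))
            external_plans.append((src, s, L, tgt))
            break
        else:
            raise CapacityError("could not place external event")

    per_region_events: dict = {rid: [] for rid in region_ids}  # (kind, length)
    caps = {rid: max(1, len(a_order[rid]) // 12) for rid in region_ids}
    for _ in range(n_internal):
        open_regions = [rid for rid in region_ids
                        if len(per_region_events[rid]) < caps[rid]]
        if not open_regions:
            raise CapacityError("could not place internal event")
        rid = open_regions[int(rng.integers(0, len(open_regions)))]
        inv = rng.random() < p_inversion
        lo = 2 if inv else 1
        hi = max(lo, max_block_genes)
        L = int(rng.integers(lo, hi + 1))
        per_region_events[rid].append(
            ("inversion" if inv else "internal_translocation", L)
        )

    internal_plans: dict = {}  # rid -> [(kind, start, length, insert_gap|None)]
    for rid in region_ids:
        events = per_region_events[rid]
        if not events:
            internal_plans[rid] = []
            continue
        plan = _plan_region_events(rng, len(a_order[rid]), events,
                                   blocked=ext_blocked[rid])
        if plan is None:
            raise CapacityError(
                f"could not place {len(events)} internal event(s) in region {rid}"
            )
        internal_plans[rid] = plan
    return external_plans, internal_plans


def _build_orders(rng, region_ids, a_order, partners, external_plans,
                  internal_plans):
    """Apply the planned events to per-region B-gene order lists."""
    orders: dict = {rid: [partners[a] for a in a_order[rid]] for rid in region_ids}
    flipped: set = set()
    events: list[PlantedEvent] = []
    moved_out: dict = {rid: set() for rid in region_ids}

    for src, s, L, tgt in external_plans:
        run_a = a_order[src][s : s + L]
        run_b = [partners[a] for a in run_a]
        for bid in run_b:
            orders[src].remove(bid)
        gap = int(rng.integers(0, len(orders[tgt]) + 1))
        orders[tgt][gap:gap] = run_b
        moved_out[src].update(run_a)
        events.append(PlantedEvent(kind="external_translocation",
                                   pairs=tuple(zip(run_a, run_b)),
                                   region_id=src, target_region_id=tgt))

    for rid in region_ids:
        order = orders[rid]
        a_index = {partners[a]: i for i, a in enumerate(a_order[rid])}
        invs = [(s, L) for kind, s, L, _g in internal_plans[rid] if kind == "inversion"]
        trans = [(s, L, g) for kind, s, L, g in internal_plans[rid]
                 if kind == "internal_translocation"]

        # inversions: reverse the run's B-genes in place, flip strands
        for s, L in invs:
            run_a = a_order[rid][s : s + L]
            run_b = [partners[a] for a in run_a]
            i0 = order.index(run_b[0])
            order[i0 : i0 + L] = run_b[::-1]
            flipped.update(run_b)
            events.append(PlantedEvent(kind="inversion",
                                       pairs=tuple(zip(run_a, run_b)),
                                       region_id=rid))

        # translocations: remove the run, reinsert before the anchor gene
        moved_ids = set()
        for s, L, _g in trans:
            moved_ids.update(partners[a] for a in a_order[rid][s : s + L])
        for s, L, gap in trans:
            run_a = a_order[rid][s : s + L]
            run_b = [partners[a] for a in run_a]
            for bid in run_b:
                order.remove(bid)
            # anchor: first non-event B-gene of this region with A-index >= gap
            anchor_pos = len(order)
            for j, bid in enumerate(order):
                if bid in moved_ids or bid not in a_index:
                    continue
                if (a_index[bid] >= gap
                        and a_order[rid][a_index[bid]] not in moved_out[rid]):
                    anchor_pos = j
                    break
            order[anchor_pos:anchor_pos] = run_b
            events.append(PlantedEvent(kind="internal_translocation",
                                       pairs=tuple(zip(run_a, run_b)),
                                       region_id=rid))
    return orders, flipped, events, moved_out


def _plan_region_events(rng, G: int, events, blocked: set, attempts: int = 300):
    """Choose disjoint runs (and insertion gaps for translocations) for one
    region such that every backbone segment stays strictly longer than the
    longest planted translocation. Returns list of (kind, start, length,
    insert_gap|None) or None if no placement was found.

    A run may sit flush against a region edge (no backbone piece there),
    but any nonempty backbone piece — between runs or between a run and an
    edge — must hold more than C genes, C being the longest translocation.
    """
    trans_lengths = [L for kind, L in events if kind == "internal_translocation"]
    C = max(trans_lengths) if trans_lengths else 0
    min_gap = C + 1 if C else 1
    for _ in range(attempts):
        runs = []
        ok = True
        for kind, L in events:
            for _try in range(50):
                s = int(rng.integers(0, G - L + 1))
                cand = set(range(s, s + L))
                if cand & blocked:
                    continue
                if not (s == 0 or s >= min_gap):
                    continue
                if not (s + L == G or s + L + min_gap <= G):
                    continue
                if all(s + L + min_gap <= rs or re + min_gap <= s
                       for rs, re, _k, _L in runs):
                    runs.append((s, s + L, kind, L))
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        plan = []
        runs.sort()
        run_spans = [(rs, re) for rs, re, _k, _L in runs]
        for rs, re, kind, L in runs:
            if kind == "inversion":
                plan.append((kind, rs, L, None))
                continue
            gaps = []
            for g in range(0, G + 1):
                if rs <= g <= re:  # would reinsert at (or inside) the origin
                    continue
                if any(s0 < g < e0 for s0, e0 in run_spans):  # inside a run
                    continue
                # backbone piece containing g must split into parts that are
                # empty or longer than C
                piece_lo, piece_hi = 0, G
                for s0, e0 in run_spans:
                    if e0 <= g:
                        piece_lo = max(piece_lo, e0)
                    if s0 >= g:
                        piece_hi = min(piece_hi, s0)
                left, right = g - piece_lo, piece_hi - g
                if (left == 0 or left >= min_gap) and (right == 0 or right >= min_gap):
                    gaps.append(g)
            if not gaps:
                break
            plan.append((kind, rs, L, int(gaps[int(rng.integers(0, len(gaps)))])))
        if len(plan) != len(events):
            continue
        return plan
    return None


def _validate_region(rid, a_ids, b_order, partners, plan, moved_out):
    """Check the planted geometry preconditions on the final permutation."""
    retained = [a for a in a_ids if a not in moved_out]
    b_rank = {bid: i for i, bid in enumerate(b_order)}
    pi = _collapse_ranks([b_rank[partners[a]] for a in retained])
    strips = strip_decomposition(pi)
    pos_of = {a: i for i, a in enumerate(retained)}

    run_members = []
    C = 0
    for kind, s, L, _gap in plan:
        members = frozenset(pos_of[a_ids[i]] for i in range(s, s + L))
        run_members.append((kind, members))
        if kind == "internal_translocation":
            C = max(C, L)

    strip_sets = [frozenset(range(st.start, st.end)) for st in strips]
    planted_sets = {members for _k, members in run_members}
    for kind, members in run_members:
        if members not in strip_sets:
            raise CapacityError(
                f"region {rid}: planted run does not surface as one segment"
            )
        st = strips[strip_sets.index(members)]
        if kind == "inversion" and st.direction != -1:
            raise CapacityError(f"region {rid}: planted inversion not reversed")
        if kind == "internal_translocation" and st.direction == -1:
            raise CapacityError(f"region {rid}: planted translocation reversed")
    if C:
        for st, sset in zip(strips, strip_sets):
            if sset in planted_sets:
                continue
            if st.size <= C:
                raise CapacityError(
                    f"region {rid}: backbone segment of {st.size} gene(s) not "
                    f"longer than the largest planted translocation ({C})"
                )


# ---------------------------------------------------------------------------
# feature tracks and sequences
# ---------------------------------------------------------------------------


def generate_track_pair(
    dataset: GenomePairDataset, conservation: float, seed=None
) -> tuple[FeatureTrack, FeatureTrack, dict]:
    """Matched weighted tracks: one element per gene whose weight mixes a
    shared per-ortholog latent value with independent noise.

    ``conservation`` c in [0, 1] is the shared-variance fraction:
    value = sqrt(c) * shared + sqrt(1 - c) * noise. At c = 1 both species
    get identical per-gene values; at c = 0 they are independent.
    """
    if not (0.0 <= conservation <= 1.0):
        raise ValueError("conservation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    c = float(conservation)
    w_shared, w_noise = np.sqrt(c), np.sqrt(1.0 - c)

    partner: dict = {}
    best: dict = {}
    for ln in dataset.links:
        if ln.gene_A not in best or ln.combined_identity > best[ln.gene_A]:
            best[ln.gene_A] = ln.combined_identity
            partner[ln.gene_A] = ln.gene_B

    value: dict = {}
    for g in dataset.genes_A:
        shared = rng.normal()
        value[g.id] = w_shared * shared + w_noise * rng.normal()
        b = partner.get(g.id)
        if b is not None:
            value[b] = w_shared * shared + w_noise * rng.normal()
    for g in dataset.genes_B:
        if g.id not in value:
            value[g.id] = rng.normal()

    track_A = FeatureTrack(
        elements=[(g.chromosome, g.start, g.end, float(value[g.id]))
                  for g in dataset.genes_A],
        has_weights=True,
    )
    track_B = FeatureTrack(
        elements=[(g.chromosome, g.start, g.end, float(value[g.id]))
                  for g in dataset.genes_B],
        has_weights=True,
    )
    return track_A, track_B, chromosome_sizes(dataset)


def generate_region_fasta(
    dataset: GenomePairDataset,
    seed=None,
    bp_per_region: int = 3_000,
    mutation_rate: float = 0.05,
) -> tuple[dict, dict]:
    """Per-region nucleotide sequences for both species: species A random,
    species B a point-mutated copy. Returns two {region_id: sequence}."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs_A: dict = {}
    seqs_B: dict = {}
    for r in dataset.regions:
        a = rng.integers(0, 4, size=bp_per_region)
        mut = rng.random(bp_per_region) < mutation_rate
        b = np.where(mut, (a + rng.integers(1, 4, size=bp_per_region)) % 4, a)
        seqs_A[r.region_id] = "".join(bases[a])
        seqs_B[r.region_id] = "".join(bases[b])
    return seqs_A, seqs_B


# ---------------------------------------------------------------------------
# ground-truth comparison helpers
# ---------------------------------------------------------------------------


def _canonical(pairs) -> frozenset:
    return frozenset(frozenset(p) for p in pairs)


def truth_event_set(truth: PlantedTruth) -> set:
    """Canonical {(kind, pair-set)} representation of the planted events."""
    return {(ev.kind, _canonical(ev.pairs)) for ev in truth.events}


def detected_event_set(result: RefinementResult) -> set:
    """Canonical {(kind, pair-set)} representation of detected blocks and
    external regions, comparable with :func:`truth_event_set`."""
    out = set()
    for r in result.refined:
        pairs = [(p.gene_A, p.gene_B) for p in r.member_pairs]
        if r.type == "internal":
            kind = ("inversion" if r.rearrangement == "inversion"
                    else "internal_translocation")
            out.add((kind, _canonical(pairs)))
        elif r.type == "external":
            out.add(("external_translocation", _canonical(pairs)))
    return out


def block_pair_sets(result: RefinementResult) -> set:
    """Species-agnostic pair-sets of all derived (block/external) regions,
    for reference-genome symmetry comparisons."""
    return {
        _canonical([(p.gene_A, p.gene_B) for p in r.member_pairs])
        for r in result.refined
        if r.type != "original"
    }
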