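"""Ortholog resolution: grouping, one-to-many reduction, symmetrization
and order-based splitting."""

import numpy as np
import pytest

from syntrefine import simulate
from syntrefine.model import Gene, OrthologGroup, OrthologyLink, SyntenicRegionPair
from syntrefine.rearrange import refine_all
from syntrefine.resolve import (
    group_orthologs,
    reduce_one_to_many,
    resolve_region,
    split_symmetric_group,
    symmetrize_group,
)

from conftest import make_gene


def _genes(ids, species, spacing=10_000):
    return [make_gene(gid, species, start=spacing * (i + 1))
            for i, gid in enumerate(ids)]


def _group(genes_a_ids, genes_b_ids, link_specs):
    """link_specs: [(gene_A, gene_B, identity)]."""
    ga = _genes(genes_a_ids, "A")
    gb = _genes(genes_b_ids, "B")
    links = [OrthologyLink(gene_A=a, gene_B=b, identity_AB=i, identity_BA=i)
             for a, b, i in link_specs]
    groups = group_orthologs(ga, gb, links)
    groups = [g for g in groups if g.cls != "no_ortholog"]
    assert len(groups) == 1
    return groups[0]


class TestGrouping:
    def test_disjoint_one_to_one_links(self):
        ga = _genes(["a1", "a2", "a3"], "A")
        gb = _genes(["b1", "b2", "b3"], "B")
        links = [OrthologyLink(gene_A=f"a{i}", gene_B=f"b{i}",
                               identity_AB=90, identity_BA=90) for i in (1, 2, 3)]
        groups = group_orthologs(ga, gb, links)
        assert [g.cls for g in groups] == ["one_internal"] * 3

    def test_one_to_many_forms_single_group(self):
        group = _group(["a1"], ["b1", "b2"], [("a1", "b1", 90), ("a1", "b2", 75)])
        assert (group.n, group.m, group.cls) == (1, 2, "many_internal")

    def test_unlinked_genes_become_no_ortholog_singletons(self):
        ga = _genes(["a1", "a2"], "A")
        gb = _genes(["b1"], "B")
        links = [OrthologyLink(gene_A="a1", gene_B="b1", identity_AB=90,
                               identity_BA=90)]
        groups = group_orthologs(ga, gb, links)
        assert [g.cls for g in groups] == ["one_internal", "no_ortholog"]

    def test_components_match_networkx_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        for _ in range(20):
            na, nb = 10, 10
            ga = _genes([f"a{i}" for i in range(na)], "A")
            gb = _genes([f"b{i}" for i in range(nb)], "B")
            links = [
                OrthologyLink(gene_A=f"a{int(rng.integers(na))}",
                              gene_B=f"b{int(rng.integers(nb))}",
                              identity_AB=80, identity_BA=80)
                for _ in range(int(rng.integers(1, 15)))
            ]
            links = list({(ln.gene_A, ln.gene_B): ln for ln in links}.values())
            groups = group_orthologs(ga, gb, links)
            got = {frozenset(g.genes_A) | frozenset(g.genes_B)
                   for g in groups if g.cls != "no_ortholog"}
            graph = nx.Graph()
            for ln in links:
                graph.add_edge(ln.gene_A, ln.gene_B)
            want = {frozenset(c) for c in nx.connected_components(graph)}
            assert got == want


class TestReduceOneToMany:
    def test_highest_identity_wins(self):
        group = _group(["a1"], ["b1", "b2"], [("a1", "b1", 90), ("a1", "b2", 75)])
        pair, losers = reduce_one_to_many(group)
        assert (pair.gene_A, pair.gene_B) == ("a1", "b1")
        assert losers == ["b2"]

    def test_tie_broken_by_rank_distance(self):
        # a1 at A-rank 0; b1 at B-rank 0, b2 at B-rank 1: equal identity,
        # b1 is positionally closer
        group = _group(["a1"], ["b1", "b2"], [("a1", "b1", 80), ("a1", "b2", 80)])
        pair, _ = reduce_one_to_many(group)
        assert pair.gene_B == "b1"

    def test_symmetric_group_is_contract_error(self):
        group = _group(["a1", "a2"], ["b1", "b2"],
                       [("a1", "b1", 90), ("a2", "b2", 90),
                        ("a1", "b2", 70), ("a2", "b1", 70)])
        with pytest.raises(ValueError):
            reduce_one_to_many(group)

    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            idents = np.round(rng.uniform(50, 100, size=5), 3)
            specs = [("a1", f"b{j}", float(idents[j])) for j in range(5)]
            group = _group(["a1"], [f"b{j}" for j in range(5)], specs)
            pair, _ = reduce_one_to_many(group)
            best = max(range(5), key=lambda j: (idents[j], -j))
            assert pair.gene_B == f"b{best}"


class TestSymmetrize:
    def test_three_vs_two_removes_lowest_average(self):
        group = _group(["a1", "a2", "a3"], ["b1", "b2"],
                       [("a1", "b1", 95), ("a2", "b2", 85), ("a3", "b1", 60),
                        ("a1", "b2", 90), ("a2", "b1", 80)])
        trimmed, removed = symmetrize_group(group)
        assert removed == ["a3"]
        assert (trimmed.n, trimmed.m) == (2, 2)

    def test_symmetric_group_is_noop(self):
        group = _group(["a1", "a2"], ["b1", "b2"],
                       [("a1", "b1", 90), ("a2", "b2", 90), ("a1", "b2", 70)])
        trimmed, removed = symmetrize_group(group)
        assert removed == [] and trimmed is group

    def test_trim_count_is_size_difference(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            specs = [(f"a{i}", f"b{j}", float(np.round(rng.uniform(50, 100), 3)))
                     for i in range(n) for j in range(m)
                     if rng.random() < 0.6] or [("a0", "b0", 80.0)]
            # ensure connectivity with a star through a0/b0
            specs += [(f"a{i}", "b0", 55.0) for i in range(n)]
            specs += [("a0", f"b{j}", 55.0) for j in range(m)]
            dedup = {(a, b): (a, b, i) for a, b, i in specs}
            group = _group([f"a{i}" for i in range(n)],
                           [f"b{j}" for j in range(m)], list(dedup.values()))
            _, removed = symmetrize_group(group)
            assert len(removed) == abs(n - m)

    def test_five_vs_three_matches_bruteforce_ranking(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            specs = [(f"a{i}", f"b{j}", float(np.round(rng.uniform(50, 100), 3)))
                     for i in range(5) for j in range(3)]
            group = _group([f"a{i}" for i in range(5)],
                           [f"b{j}" for j in range(3)], specs)
            _, removed = symmetrize_group(group)
            avg = {f"a{i}": np.mean([s[2] for s in specs if s[0] == f"a{i}"])
                   for i in range(5)}
            want = sorted(avg, key=lambda g: (avg[g], g))[:2]
            assert sorted(removed) == sorted(want)


class TestSplit:
    def test_pairs_by_genomic_order_not_by_links(self):
        # A-genes at ranks 0,1; B-genes at ranks 0,1; the links are crossed
        # (plus one straight link for connectivity), but order decides
        group = _group(["a3", "a5"], ["b2", "b7"],
                       [("a3", "b7", 90), ("a5", "b2", 88), ("a3", "b2", 60)])
        pairs = split_symmetric_group(group)
        assert [(p.gene_A, p.gene_B) for p in pairs] == [("a3", "b2"), ("a5", "b7")]
        assert all(p.provenance == "order_split" for p in pairs)

    def test_singleton_group_gives_single_pair(self):
        group = _group(["a1"], ["b1"], [("a1", "b1", 90)])
        assert len(split_symmetric_group(group)) == 1

    def test_asymmetric_input_is_contract_error(self):
        group = _group(["a1"], ["b1", "b2"], [("a1", "b1", 90), ("a1", "b2", 80)])
        with pytest.raises(ValueError):
            split_symmetric_group(group)

    def test_matches_sort_and_zip_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            specs = [(f"a{i}", f"b{j}", float(np.round(rng.uniform(50, 100), 3)))
                     for i in range(4) for j in range(4)]
            group = _group([f"a{i}" for i in range(4)],
                           [f"b{j}" for j in range(4)], specs)
            pairs = split_symmetric_group(group)
            assert [(p.gene_A, p.gene_B) for p in pairs] == [
                (f"a{i}", f"b{i}") for i in range(4)]


def _make_region(start=0, end=10_000_000):
    return SyntenicRegionPair(region_id="r", chrom_A="chrA1", start_A=start,
                              end_A=end, chrom_B="chrB1", start_B=start, end_B=end)


class TestResolveRegion:
    def test_clean_region_resolves_without_removals(self):
        ga = _genes([f"a{i}" for i in range(5)], "A")
        gb = _genes([f"b{i}" for i in range(5)], "B")
        links = [OrthologyLink(gene_A=f"a{i}", gene_B=f"b{i}",
                               identity_AB=90, identity_BA=90) for i in range(5)]
        report = resolve_region(_make_region(), ga, gb, links)
        assert len(report.pairs) == 5 and report.removed_genes == []

    def test_overlapping_genes_all_excluded(self):
        ga = _genes(["a1", "a2", "a3"], "A")
        # a2/a3 overlap in coordinates
        ga[2] = make_gene("a3", "A", start=ga[1].start + 100, end=ga[1].end + 100)
        gb = _genes(["b1", "b2", "b3"], "B")
        links = [OrthologyLink(gene_A=f"a{i}", gene_B=f"b{i}",
                               identity_AB=90, identity_BA=90) for i in (1, 2, 3)]
        report = resolve_region(_make_region(), ga, gb, links)
        assert report.removed_ids("overlap_excluded") == {"a2", "a3"}
        assert [p.gene_A for p in report.pairs] == ["a1"]

    def test_mixed_group_configuration(self):
        """One 1-to-2 group, one 3-vs-2 group, one orphan gene: resolution
        removes the duplicate and the asymmetric extra, leaves the orphan
        unpaired for external detection."""
        ga = _genes([f"a{i}" for i in range(6)], "A")
        gb = _genes([f"b{i}" for i in range(5)], "B")
        links = [
            # a0 -> b0 (strong), b1 (weak): one-to-many
            OrthologyLink(gene_A="a0", gene_B="b0", identity_AB=92, identity_BA=92),
            OrthologyLink(gene_A="a0", gene_B="b1", identity_AB=70, identity_BA=70),
            # a1,a2,a3 x b2,b3: asymmetric many-to-many, a3 weakest
            OrthologyLink(gene_A="a1", gene_B="b2", identity_AB=90, identity_BA=90),
            OrthologyLink(gene_A="a2", gene_B="b3", identity_AB=88, identity_BA=88),
            OrthologyLink(gene_A="a3", gene_B="b2", identity_AB=55, identity_BA=55),
            OrthologyLink(gene_A="a1", gene_B="b3", identity_AB=85, identity_BA=85),
            # a4 <-> b4 plain
            OrthologyLink(gene_A="a4", gene_B="b4", identity_AB=95, identity_BA=95),
            # a5 has no ortholog here (orphan; candidate external)
        ]
        report = resolve_region(_make_region(), ga, gb, links)
        assert report.removed_ids("one_to_many_loser") == {"b1"}
        assert report.removed_ids("asymmetry_trim") == {"a3"}
        assert report.removed_ids("no_ortholog") == {"a5"}
        got = {(p.gene_A, p.gene_B) for p in report.pairs}
        assert got == {("a0", "b0"), ("a1", "b2"), ("a2", "b3"), ("a4", "b4")}

    def test_gene_conservation_and_uniqueness_over_random_regions(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            na, nb = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            ga = _genes([f"a{i}" for i in range(na)], "A")
            gb = _genes([f"b{j}" for j in range(nb)], "B")
            links = list({
                (f"a{int(rng.integers(na))}", f"b{int(rng.integers(nb))}"): None
                for _ in range(int(rng.integers(0, 20)))
            })
            links = [OrthologyLink(gene_A=a, gene_B=b,
                                   identity_AB=float(np.round(rng.uniform(50, 100), 3)),
                                   identity_BA=float(np.round(rng.uniform(50, 100), 3)))
                     for a, b in links]
            report = resolve_region(_make_region(), ga, gb, links)
            seen = [g for p in report.pairs for g in (p.gene_A, p.gene_B)]
            assert len(seen) == len(set(seen))  # each gene in <= 1 pair
            accounted = set(seen) | report.removed_ids()
            assert accounted == {g.id for g in ga} | {g.id for g in gb}

    def test_idempotent_on_resolved_pairs(self):
        ga = _genes([f"a{i}" for i in range(4)], "A")
        gb = _genes([f"b{i}" for i in range(4)], "B")
        links = [OrthologyLink(gene_A=f"a{i}", gene_B=f"b{i}",
                               identity_AB=90, identity_BA=90) for i in range(4)]
        first = resolve_region(_make_region(), ga, gb, links)
        again = resolve_region(_make_region(), ga, gb, [
            OrthologyLink(gene_A=p.gene_A, gene_B=p.gene_B,
                          identity_AB=90, identity_BA=90)
            for p in first.pairs
        ])
        assert [(p.gene_A, p.gene_B) for p in again.pairs] == [
            (p.gene_A, p.gene_B) for p in first.pairs]


class TestDuplicationFixtures:
    def test_intended_losers_are_exactly_the_removed_genes(self):
        for seed in range(8):
            dataset, _ = simulate.generate_genome_pair(5, 20, seed=seed)
            dataset, truth = simulate.plant_rearrangements(
                dataset, n_internal=0, n_external=0, p_duplication=0.15,
                seed=seed + 100)
            result = refine_all(dataset)
            removed = set()
            for rep in result.reports.values():
                removed |= rep.removed_ids("one_to_many_loser", "asymmetry_trim")
            assert removed == set(truth.intended_losers)
            assert truth.intended_losers  # fixtures actually contain duplications
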