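"""Flanking windows, block detection, tandem rule, quality, ancestral groups."""

import random

import networkx as nx
import pytest

from duphist.catalog import CatalogError, CatalogSet, GeneCatalog, GeneModel
from duphist.synteny import (
    SyntenyBlock,
    ancestral_groups,
    classify_family_pairs,
    cross_species_synteny,
    detect_block,
    flanking_window,
    intra_species_synteny,
    synteny_quality,
    tandem_clusters,
    tandem_test,
)


def _gene(gene_id, chrom, start, end, family=False):
    length = 3 * ((end - start + 1) // 3) or 3
    return GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=end,
                     strand="+", cds="ATG" + "GGC" * (length // 3),
                     is_family=family, exon_lengths=(length,))


def _chain(species, chrom, ids, family=(), gap=2000, span=1200):
    genes, pos = [], 1
    for gid in ids:
        genes.append(_gene(gid, chrom, pos + gap, pos + gap + span - 1,
                           family=gid in family))
        pos = pos + gap + span
    return genes


def _catalog(species, genes_by_chrom):
    return GeneCatalog(species=species, chromosomes=genes_by_chrom)


@pytest.fixture
def twin_chromosomes():
    """Two chromosomes that are gene-order copies: a1..a8 and b1..b8,
    with ai homologous to bi, anchors a4/b4 family members."""
    ids_a = [f"a{i}" for i in range(8)]
    ids_b = [f"b{i}" for i in range(8)]
    cat = _catalog("sp", {
        "c1": _chain("sp", "c1", ids_a, family={"a4"}),
        "c2": _chain("sp", "c2", ids_b, family={"b4"}),
    })
    graph = nx.Graph()
    for i in range(8):
        graph.add_edge(f"a{i}", f"b{i}", score=500.0)
    return cat, graph


class TestFlankingWindow:
    def test_edge_truncation(self, small_catalog):
        first = small_catalog.genes()[0]
        up, down = flanking_window(small_catalog, first.gene_id, k=50)
        assert up == []
        assert len(down) == len(small_catalog) - 1

    def test_middle_gene_small_k(self, small_catalog):
        mid = small_catalog.genes()[5]
        up, down = flanking_window(small_catalog, mid.gene_id, k=2)
        assert len(up) == 2 and len(down) == 2
        assert mid.gene_id not in up + down

    def test_unknown_gene(self, small_catalog):
        with pytest.raises(CatalogError):
            flanking_window(small_catalog, "nope")


class TestDetectBlock:
    def test_full_collinearity(self, twin_chromosomes):
        cat, graph = twin_chromosomes
        blk = detect_block("a4", "b4", CatalogSet([cat]), graph, k=50)
        assert blk is not None
        assert blk.match_count == 7  # all non-anchor genes matched

    def test_threshold_at_exactly_three_matches(self, twin_chromosomes):
        cat, _ = twin_chromosomes
        cats = CatalogSet([cat])
        for n_edges, expected in [(3, True), (2, False)]:
            graph = nx.Graph()
            graph.add_edge("a4", "b4", score=900.0)
            for i in range(n_edges):
                graph.add_edge(f"a{i}", f"b{i}", score=500.0)
            blk = detect_block("a4", "b4", cats, graph, k=50)
            assert (blk is not None) is expected

    def test_one_to_one_matching_defeats_repetitive_flank(self, twin_chromosomes):
        """One promiscuous flanking gene homologous to many cannot satisfy
        the >= 3 rule by itself."""
        cat, _ = twin_chromosomes
        graph = nx.Graph()
        graph.add_edge("a4", "b4", score=900.0)
        for i in (0, 1, 2):
            graph.add_edge("a0", f"b{i}", score=500.0)  # a0 matches 3 genes
        blk = detect_block("a4", "b4", CatalogSet([cat]), graph, k=50)
        assert blk is None

    def test_non_family_anchor_rejected_by_default(self, twin_chromosomes):
        cat, graph = twin_chromosomes
        graph.add_edge("a0", "b0", score=1.0)
        with pytest.raises(CatalogError):
            detect_block("a0", "b0", CatalogSet([cat]), graph)


class TestSyntenyQuality:
    def test_perfect_collinearity(self):
        blk = SyntenyBlock("a", "b", "s", "s", tuple(("x", "y") for _ in range(9)),
                           segment_size_a=10, segment_size_b=10)
        assert synteny_quality(blk) == pytest.approx(100.0)

    def test_partial_match_closed_form(self):
        # 5 matches including the anchor over segments of 10 and 12 genes
        blk = SyntenyBlock("a", "b", "s", "s", tuple(("x", "y") for _ in range(4)),
                           segment_size_a=10, segment_size_b=12)
        assert synteny_quality(blk) == pytest.approx(45.45, abs=0.01)

    def test_never_exceeds_hundred(self, twin_chromosomes):
        cat, graph = twin_chromosomes
        blk = detect_block("a4", "b4", CatalogSet([cat]), graph, k=50)
        assert blk.quality <= 100.0
        assert blk.quality == pytest.approx(100.0)  # fully matched twins


class TestTandemRule:
    def _pair_catalog(self, start_b, end_b, n_between=0, family_between=False):
        genes = [_gene("fam1", "sc58", 1_216_903, 1_220_688, family=True)]
        for i in range(n_between):
            s = 1_221_000 + i * 1500
            genes.append(_gene(f"mid{i}", "sc58", s, s + 900,
                               family=family_between))
        genes.append(_gene("fam2", "sc58", start_b, end_b, family=True))
        return _catalog("cp", {"sc58": genes})

    def test_printed_coordinates_are_tandem(self):
        # spans 1,216,903-1,220,688 and 1,233,011-1,236,967: ~12.3 kb apart
        cat = self._pair_catalog(1_233_011, 1_236_967)
        assert tandem_test("fam1", "fam2", cat)
        assert tandem_test("fam2", "fam1", cat)  # symmetric

    def test_61_kb_apart_is_not_tandem(self):
        cat = self._pair_catalog(1_220_688 + 61_001, 1_220_688 + 61_001 + 3900)
        assert not tandem_test("fam1", "fam2", cat)

    def test_six_intervening_loci_is_not_tandem(self):
        cat = self._pair_catalog(1_233_011, 1_236_967, n_between=6)
        assert not tandem_test("fam1", "fam2", cat)
        cat5 = self._pair_catalog(1_233_011, 1_236_967, n_between=5)
        assert tandem_test("fam1", "fam2", cat5)

    def test_family_genes_between_do_not_count(self):
        cat = self._pair_catalog(1_233_011, 1_236_967, n_between=6,
                                 family_between=True)
        assert tandem_test("fam1", "fam2", cat)

    def test_clusters_merge_transitively(self):
        genes = []
        pos = 1000
        for i in range(4):
            genes.append(_gene(f"f{i}", "c1", pos, pos + 1200, family=True))
            pos += 40_000  # consecutive pairs within 60 kb, ends are not
        cat = _catalog("sp", {"c1": genes})
        assert tandem_clusters(cat) == [["f0", "f1", "f2", "f3"]]


class TestAncestralGroups:
    def _blocks(self, edges, species_of):
        blocks = []
        for a, b in edges:
            blocks.append(SyntenyBlock(a, b, species_of[a], species_of[b],
                                       tuple(("x", "y") for _ in range(3)), 60, 60))
        return blocks

    def _cats(self, species_of):
        per = {}
        for g, sp in species_of.items():
            per.setdefault(sp, []).append(g)
        cats = []
        for sp, ids in per.items():
            cats.append(_catalog(sp, {"c1": _chain(sp, "c1", sorted(ids),
                                                   family=set(ids))}))
        return CatalogSet(cats)

    def test_connected_component_forms_one_group(self):
        """A chain of within- and cross-species blocks collapses into a single
        ancestral locus spanning all four species."""
        species_of = {"At3": "at", "At6": "at", "Pt5": "pt", "Pt6": "pt",
                      "Vv8": "vv", "Cp3": "cp"}
        edges = [("At3", "Pt5"), ("At3", "Pt6"), ("Pt5", "Vv8"),
                 ("Vv8", "Cp3"), ("At3", "At6")]
        groups = ancestral_groups(self._blocks(edges, species_of),
                                  self._cats(species_of))
        assert len(groups) == 1
        assert groups[0].group_id == "A"
        assert sorted(groups[0].all_members()) == sorted(species_of)

    def test_no_blocks_no_groups(self):
        assert ancestral_groups([], CatalogSet([])) == []

    def test_labeling_invariant_to_block_order(self):
        species_of = {f"g{i}": "s1" for i in range(6)}
        edges = [("g0", "g1"), ("g1", "g2"), ("g3", "g4")]
        cats = self._cats(species_of)
        blocks = self._blocks(edges, species_of)
        ref = [(g.group_id, g.all_members()) for g in ancestral_groups(blocks, cats)]
        rnd = random.Random(0)
        for _ in range(5):
            shuffled = blocks[:]
            rnd.shuffle(shuffled)
            got = [(g.group_id, g.all_members())
                   for g in ancestral_groups(shuffled, cats)]
            assert got == ref
        # bigger component first
        assert ref[0][0] == "A" and len(ref[0][1]) == 3


class TestClassification:
    def test_tandem_wins_over_segmental(self):
        ids = [f"g{i}" for i in range(6)]
        genes = _chain("sp", "c1", ids, family={"g2", "g3"}, gap=2000)
        cat = _catalog("sp", {"c1": genes})
        cats = CatalogSet([cat])
        blk = SyntenyBlock("g2", "g3", "sp", "sp",
                           tuple(("x", "y") for _ in range(3)), 10, 10)
        labels = classify_family_pairs([blk], cats)
        assert labels[("g2", "g3")] == "tandem"


class TestEndToEndSynteny:
    def test_wgd_blocks_and_cross_species(self):
        from duphist.homology import all_vs_all
        from duphist.simulate import SimConfig, apply_wgd, build_ancestral_genome, speciate
        from duphist.synteny import build_homology_graph

        anc = build_ancestral_genome(SimConfig(
            n_chromosomes=1, genes_per_chromosome=15, family_founder_count=1, seed=12))
        dup, records = apply_wgd(anc, 0.1, 1.0, "e", seed=1)
        hits = all_vs_all(dup)
        graph = build_homology_graph(hits)
        blocks = intra_species_synteny(dup, graph)
        fam_pairs = {tuple(sorted((r.parent_gene, r.child_gene)))
                     for r in records
                     if dup.get(r.parent_gene).is_family and dup.get(r.child_gene).is_family}
        assert {tuple(sorted(b.anchors)) for b in blocks} == fam_pairs
        # every block's flanks are full copies: match count near 2k
        for b in blocks:
            assert b.match_count >= 10

        cat_a, _ = speciate(dup, "x", 0.2, seed=5)
        cat_b, _ = speciate(dup, "y", 0.2, seed=6)
        hits2 = all_vs_all([cat_a, cat_b])
        graph2 = build_homology_graph(hits2)
        xblocks = cross_species_synteny(cat_a, cat_b, graph2)
        # two family genes per species -> 4 homologous cross pairs, all collinear
        assert len(xblocks) == 4
        assert all(b.species_a != b.species_b for b in xblocks)
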