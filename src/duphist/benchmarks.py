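"""Planted-truth recovery studies: the package validated against its simulator.

Each function runs a self-contained experiment at a given seed and returns
the measured quantities; the test suite asserts on them and the acceptance
script reports them. Problem sizes are desk-scale (tens of genes per
chromosome, 20 replicate seeds) — large enough for stable rates, small
enough to run on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np

from . import homology, synteny
from .catalog import CatalogSet
from .dating import block_median_ks
from .kaks import kaks_for_cds_pair
from .phylo import DistanceMatrix, neighbor_joining
from .simulate import evolve_cds_pair, expected_pair_era, random_cds, simulate_clade


def kaks_recovery(seed: int, n_pairs: int = 100, n_codons: int = 1000,
                  target_ks: float = 0.5, target_omega: float = 0.2) -> dict:
    """Estimate Ks and omega on simulated pairs; return the means.

    Each replicate evolves a fresh random CDS at the target divergence and
    re-estimates it through the full protein-guided NG86 path.
    """
    rng = np.random.default_rng(seed)
    ks_est, om_est = [], []
    for _ in range(n_pairs):
        cds = random_cds(rng, n_codons)
        mutant = evolve_cds_pair(cds, target_ks, target_omega, rng)
        res = kaks_for_cds_pair(cds, mutant)
        ks_est.append(res.Ks)
        om_est.append(res.omega)
    return dict(mean_ks=float(np.mean(ks_est)), mean_omega=float(np.mean(om_est)),
                target_ks=target_ks, target_omega=target_omega, n=n_pairs)


def planted_event_recovery(seed: int, n_replicates: int = 20, **clade_kwargs) -> dict:
    """Score block detection, tandem classification and era assignment
    against a clade simulation's planted truth, over replicate seeds.

    Returns segmental recall, the fraction of planted tandem pairs classified
    tandem (and none segmental-only), and era-assignment accuracy for the
    dated within-species blocks.
    """
    rng = np.random.default_rng(seed)
    seg_found = seg_total = 0
    td_ok = td_total = 0
    era_ok = era_total = 0
    tandem_as_segmental = 0
    for _ in range(n_replicates):
        sim = simulate_clade(seed=int(rng.integers(0, 2**31 - 1)), **clade_kwargs)
        cats = CatalogSet(list(sim.catalogs.values()))
        blocks = []
        for sp, cat in sim.catalogs.items():
            hits = homology.all_vs_all(cat)
            graph = synteny.build_homology_graph(hits)
            blocks.extend(synteny.intra_species_synteny(cat, graph))
        detected = {tuple(sorted(b.anchors)) for b in blocks}
        truth_pairs = {tuple(sorted((r.gene_a, r.gene_b)))
                       for r in sim.segmental_truth_pairs.itertuples()}
        seg_total += len(truth_pairs)
        seg_found += len(detected & truth_pairs)

        labels = synteny.classify_family_pairs(blocks, cats)
        for r in sim.tandem_truth_pairs.itertuples():
            td_total += 1
            pair = tuple(sorted((r.gene_a, r.gene_b)))
            lab = labels.get(pair)
            td_ok += lab == "tandem"
            tandem_as_segmental += lab == "segmental"

        # era assignment on dated blocks, scored against lineage truth
        from .dating import assign_event_era
        from .pipeline import _simulation_era_config

        era_config = _simulation_era_config(sim)
        table = {}
        for blk in blocks:
            for a, b in (blk.anchors, *blk.flank_matches):
                key = tuple(sorted((a, b)))
                if key not in table:
                    table[key] = kaks_for_cds_pair(cats.get(key[0]).cds,
                                                   cats.get(key[1]).cds)
            mks, _ = block_median_ks(blk, table)
            expected = expected_pair_era(sim.lineage, *blk.anchors)
            if expected is None or mks is None:
                continue
            assigned = assign_event_era(mks, blk.species_a, era_config)
            era_total += 1
            era_ok += assigned == expected
    return dict(
        segmental_recall=seg_found / seg_total if seg_total else float("nan"),
        n_segmental=seg_total,
        tandem_accuracy=td_ok / td_total if td_total else float("nan"),
        tandem_as_segmental=tandem_as_segmental,
        n_tandem=td_total,
        era_accuracy=era_ok / era_total if era_total else float("nan"),
        n_dated_blocks=era_total,
        n_replicates=n_replicates,
    )


def random_additive_tree(rng: np.random.Generator, n_taxa: int,
                         ) -> tuple[list[str], np.ndarray]:
    """A random unrooted binary tree with branch lengths in [0.1, 1],
    returned as its (exact) leaf-to-leaf path-distance matrix."""
    import networkx as nx

    g = nx.Graph()
    g.add_edge("L0", "i0", w=float(rng.uniform(0.1, 1)))
    g.add_edge("L1", "i0", w=float(rng.uniform(0.1, 1)))
    g.add_edge("L2", "i0", w=float(rng.uniform(0.1, 1)))
    leaves = ["L0", "L1", "L2"]
    for k in range(3, n_taxa):
        u, v = list(g.edges)[rng.integers(0, g.number_of_edges())]
        w = g.edges[u, v]["w"]
        g.remove_edge(u, v)
        mid = f"i{k}"
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, w=w * split)
        g.add_edge(mid, v, w=w * (1 - split))
        leaf = f"L{k}"
        g.add_edge(mid, leaf, w=float(rng.uniform(0.1, 1)))
        leaves.append(leaf)
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i != j:
                d[i, j] = paths[a][b]
    d = (d + d.T) / 2  # exact symmetry despite float summation order
    return leaves, d


def nj_additive_recovery(seed: int, n_trees: int = 50, n_taxa: int = 8) -> dict:
    """Fraction of random additive trees NJ reconstructs exactly.

    Exactness means every leaf-to-leaf path distance of the reconstructed
    tree matches the input matrix to 1e-9 (which pins both the topology and
    all branch lengths).
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_trees):
        labels, d = random_additive_tree(rng, n_taxa)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        g = nx.Graph()
        leafmap = {}

        def walk(node):
            if not node.children:
                leafmap[node.label] = id(node)
            for child, ln in node.children:
                g.add_edge(id(node), id(child), w=ln)
                walk(child)

        walk(tree.root)
        paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
        n = len(labels)
        rec = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    rec[i, j] = paths[leafmap[a]][leafmap[b]]
        ok += bool(np.allclose(rec, d, atol=1e-9))
    return dict(recovered=ok, n_trees=n_trees, rate=ok / n_trees)
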