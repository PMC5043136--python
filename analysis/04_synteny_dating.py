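#!/usr/bin/env python
"""Microsynteny blocks within and between species, tandem arrays, block dating.

Reads catalogs and hits, detects blocks (>= 3 one-to-one flank homolog pairs
among the 50 up/downstream neighbors), classifies tandem arrays (60 kb /
<= 5 intervening non-family loci), dates each within-species block by its
median Ks, and writes blocks.tsv, tandem_clusters.tsv and the dated-pair
table under results/.
"""

import itertools
import os

import pandas as pd

from duphist.catalog import CatalogSet, import_catalog
from duphist.dating import date_blocks
from duphist.homology import HomologyHit
from duphist.kaks import kaks_for_cds_pair
from duphist.report import dated_pairs_table, synteny_quality_matrix
from duphist.synteny import (
    build_homology_graph,
    cross_species_synteny,
    intra_species_synteny,
    tandem_clusters,
)

import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from analysis_config import ERAS, SPECIES  # noqa: E402

DATA, OUT = "results/data", "results"


def main():
    catalogs = {sp: import_catalog(os.path.join(DATA, sp), sp) for sp in SPECIES}
    cats = CatalogSet(list(catalogs.values()))
    hdf = pd.read_csv(os.path.join(OUT, "hits.tsv"), sep="\t")
    hits = [HomologyHit(**r) for r in hdf.to_dict("records")]
    graph = build_homology_graph(hits)

    blocks = []
    for sp in SPECIES:
        blocks += intra_species_synteny(catalogs[sp], graph)
    for sa, sb in itertools.combinations(SPECIES, 2):
        blocks += cross_species_synteny(catalogs[sa], catalogs[sb], graph)
    print(f"{len(blocks)} blocks "
          f"({sum(b.species_a == b.species_b for b in blocks)} within-species)")

    table = {}
    for blk in blocks:
        for a, b in (blk.anchors, *blk.flank_matches):
            key = tuple(sorted((a, b)))
            if key not in table:
                table[key] = kaks_for_cds_pair(cats.get(key[0]).cds, cats.get(key[1]).cds)
    date_blocks(blocks, table, ERAS)

    dated = dated_pairs_table(blocks, table)
    dated.to_csv(os.path.join(OUT, "blocks.tsv"), sep="\t", index=False)
    within = dated[dated.era != "unassigned"]
    print("dated within-species blocks by era:")
    print(within.groupby("era").size())

    rows = [dict(species=sp, cluster=";".join(c))
            for sp in SPECIES for c in tandem_clusters(catalogs[sp])]
    pd.DataFrame(rows, columns=["species", "cluster"]).to_csv(
        os.path.join(OUT, "tandem_clusters.tsv"), sep="\t", index=False)
    print(f"tandem clusters: {rows}")

    qual = synteny_quality_matrix([b for b in blocks if b.species_a != b.species_b])
    qual.to_csv(os.path.join(OUT, "quality_matrix.tsv"), sep="\t", na_rep="")
    print("mean cross-species synteny quality (%):")
    print(qual.to_string())


if __name__ == "__main__":
    main()
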