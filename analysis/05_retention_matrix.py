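#!/usr/bin/env python
"""Ancestral-locus groups and the retention matrix.

Re-detects blocks from stored hits (cheap), merges anchors into connected
components ("A", "B", ...), lays out per-species duplicate slots, and writes
retention_matrix.tsv plus the observed/expected multiplicity report.
"""

import itertools
import os

import pandas as pd

from duphist.catalog import CatalogSet, import_catalog
from duphist.dating import build_retention_matrix, expected_multiplicity_check
from duphist.homology import HomologyHit
from duphist.synteny import (
    ancestral_groups,
    build_homology_graph,
    cross_species_synteny,
    intra_species_synteny,
    subfunctionalized_partners,
)

import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from analysis_config import ERAS, SPECIES  # noqa: E402

DATA, OUT = "results/data", "results"


def main():
    catalogs = {sp: import_catalog(os.path.join(DATA, sp), sp) for sp in SPECIES}
    cats = CatalogSet(list(catalogs.values()))
    hdf = pd.read_csv(os.path.join(OUT, "hits.tsv"), sep="\t")
    graph = build_homology_graph([HomologyHit(**r) for r in hdf.to_dict("records")])

    blocks, nblocks = [], []
    for sp in SPECIES:
        blocks += intra_species_synteny(catalogs[sp], graph)
        nblocks += subfunctionalized_partners(catalogs[sp], graph)
    for sa, sb in itertools.combinations(SPECIES, 2):
        blocks += cross_species_synteny(catalogs[sa], catalogs[sb], graph)

    groups = ancestral_groups(blocks, cats)
    print("groups:", {g.group_id: g.size for g in groups})
    matrix = build_retention_matrix(groups, blocks + nblocks, cats, ERAS)
    matrix.to_frame().to_csv(os.path.join(OUT, "retention_matrix.tsv"), sep="\t")
    print(matrix.to_frame().to_string())

    report = expected_multiplicity_check(matrix, ERAS, benchmark="s4")
    report.to_csv(os.path.join(OUT, "multiplicity.tsv"), sep="\t", index=False)
    print(report.to_string(index=False))


if __name__ == "__main__":
    main()
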