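#!/usr/bin/env python
"""All-vs-all homology search; call paralogs and reciprocal-best-hit orthologs.

Reads the catalogs written by 01_simulate_clade.py, writes hits.tsv,
paralogs.tsv, orthologs.tsv and the per-species involvement percentages
(the "x% (k/n)" figures) under results/.
"""

import itertools
import os

import pandas as pd

from duphist.catalog import CatalogSet, import_catalog
from duphist.homology import all_vs_all, call_orthologs, call_paralogs, cross_species_hits
from duphist.report import paralog_percentages

DATA, OUT = "results/data", "results"
SPECIES = ["s1", "s2", "s3", "s4"]


def main():
    catalogs = [import_catalog(os.path.join(DATA, sp), sp) for sp in SPECIES]
    cats = CatalogSet(catalogs)
    hits = all_vs_all(catalogs)
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(
        os.path.join(OUT, "hits.tsv"), sep="\t", index=False)
    print(f"{len(hits)} homology hits")

    paralogs = []
    for sp in SPECIES:
        sp_hits = [h for h in hits
                   if cats.species_of(h.query) == sp and cats.species_of(h.subject) == sp]
        paralogs.extend(call_paralogs(sp_hits, cats))
    orthologs = []
    for sa, sb in itertools.combinations(SPECIES, 2):
        ab, ba = cross_species_hits(hits, cats, sa, sb)
        orthologs.extend(call_orthologs(ab, ba, cats))

    for name, pairs in (("paralogs", paralogs), ("orthologs", orthologs)):
        pd.DataFrame([dict(gene_a=p.gene_a, gene_b=p.gene_b, species_a=p.species_a,
                           species_b=p.species_b) for p in pairs]).to_csv(
            os.path.join(OUT, f"{name}.tsv"), sep="\t", index=False)
        print(f"{len(pairs)} {name} pairs")

    pct = paralog_percentages(paralogs, catalogs)
    pct.to_csv(os.path.join(OUT, "paralog_percentages.tsv"), sep="\t", index=False)
    print(pct[["species", "formatted"]].to_string(index=False))


if __name__ == "__main__":
    main()
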