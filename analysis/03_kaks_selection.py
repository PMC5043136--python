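#!/usr/bin/env python
"""NG86 Ka/Ks and selection regimes for every called paralog/ortholog pair.

Reads pairs from results/, writes kaks.tsv and prints the regime breakdown —
the expectation for a conserved enzyme family is strong purifying selection
(omega well under 0.5) for nearly every pair.
"""

import os

import pandas as pd
from Bio import SeqIO

from duphist.kaks import kaks_for_cds_pair

DATA, OUT = "results/data", "results"
SPECIES = ["s1", "s2", "s3", "s4"]


def main():
    seqs = {}
    for sp in SPECIES:
        for rec in SeqIO.parse(os.path.join(DATA, f"{sp}.cds.fasta"), "fasta"):
            seqs[rec.id] = str(rec.seq)
    pairs = pd.concat([pd.read_csv(os.path.join(OUT, f), sep="\t")
                       for f in ("paralogs.tsv", "orthologs.tsv")])
    rows = []
    for row in pairs.itertuples():
        r = kaks_for_cds_pair(seqs[row.gene_a], seqs[row.gene_b])
        rows.append(dict(gene_a=row.gene_a, gene_b=row.gene_b,
                         kind="paralog" if row.species_a == row.species_b else "ortholog",
                         ka=r.Ka, ks=r.Ks, omega=r.omega, regime=r.regime))
    out = pd.DataFrame(rows)
    out.to_csv(os.path.join(OUT, "kaks.tsv"), sep="\t", index=False)
    print(out.groupby(["kind", "regime"]).size())
    defined = out.dropna(subset=["omega"])
    print(f"median omega {defined.omega.median():.3f}; "
          f"{(defined.omega < 0.5).mean() * 100:.1f}% under strong purifying selection")


if __name__ == "__main__":
    main()
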