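"""Tabular reports: gene inventory, dated duplicate pairs, synteny quality.

The layouts mirror the tables comparative gene-family studies publish: a
per-gene inventory (with ORF length = 3 x (protein length + 1), counting the
stop codon), a dated-pair table with block median Ks and era, and a
species-by-species lower-triangular matrix of mean synteny quality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .kaks import KaKsResult
from .synteny import SyntenyBlock


def orf_length_bp(protein_length_aa: int) -> int:
    """ORF length in bp from protein length: 3 x (aa + 1), stop included."""
    return 3 * (protein_length_aa + 1)


def gene_inventory(catalogs: list[GeneCatalog], family_only: bool = True) -> pd.DataFrame:
    rows = []
    for cat in catalogs:
        genes = cat.family_genes() if family_only else cat.genes()
        for g in genes:
            plen = len(g.protein)
            rows.append(dict(
                species=cat.species, gene_id=g.gene_id, chrom=g.chrom,
                start=g.start, end=g.end, exon_count=g.exon_count,
                protein_length_aa=plen, orf_length_bp=orf_length_bp(plen),
            ))
    return pd.DataFrame(rows, columns=["species", "gene_id", "chrom", "start", "end",
                                       "exon_count", "protein_length_aa", "orf_length_bp"])


def dated_pairs_table(blocks: list[SyntenyBlock],
                      kaks_table: dict[tuple[str, str], KaKsResult]) -> pd.DataFrame:
    rows = []
    for blk in blocks:
        res = kaks_table.get(blk.anchors, kaks_table.get(blk.anchors[::-1]))
        rows.append(dict(
            species=blk.species_a if blk.species_a == blk.species_b
            else f"{blk.species_a}/{blk.species_b}",
            gene_a=blk.anchor_a, gene_b=blk.anchor_b,
            ka=None if res is None else res.Ka,
            ks=None if res is None else res.Ks,
            block_median_ks=blk.median_ks,
            match_count=blk.match_count,
            quality=round(blk.quality, 2),
            era=blk.era if blk.era is not None else "unassigned",
        ))
    return pd.DataFrame(rows, columns=["species", "gene_a", "gene_b", "ka", "ks",
                                       "block_median_ks", "match_count", "quality", "era"])


def synteny_quality_matrix(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Lower-triangular species x species mean block quality (percent).

    Species pairs with no blocks are left blank (NA), not zero.
    """
    species = sorted({s for b in blocks for s in (b.species_a, b.species_b)})
    acc: dict[tuple[str, str], list[float]] = {}
    for b in blocks:
        key = tuple(sorted((b.species_a, b.species_b)))
        acc.setdefault(key, []).append(b.quality)
    mat = pd.DataFrame(np.nan, index=species, columns=species)
    for (s1, s2), vals in acc.items():
        lo, hi = sorted((s1, s2))
        mat.loc[hi, lo] = round(float(np.mean(vals)), 2)
    return mat


def paralog_percentages(pairs, catalogs: list[GeneCatalog]) -> pd.DataFrame:
    """Per species: fraction of family genes involved in paralog pairs.

    Formatted results-style as "x% (k/n)".
    """
    in_pairs: dict[str, set[str]] = {}
    for p in pairs:
        in_pairs.setdefault(p.species_a, set()).update((p.gene_a, p.gene_b))
    rows = []
    for cat in catalogs:
        fam = {g.gene_id for g in cat.family_genes()}
        k = len(fam & in_pairs.get(cat.species, set()))
        n = len(fam)
        pct = 100.0 * k / n if n else float("nan")
        rows.append(dict(species=cat.species, genes_in_pairs=k, family_size=n,
                         percent=round(pct, 1),
                         formatted=f"{pct:.1f}% ({k}/{n})"))
    return pd.DataFrame(rows)
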