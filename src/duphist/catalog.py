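"""Gene catalogs: ordered gene models per chromosome with sequences.

A :class:`GeneCatalog` is the in-memory container every stage of the pipeline
works on. Catalogs round-trip through plain-text files: CDS and protein FASTA
(via Biopython), GFF3 (gene/mRNA/exon/CDS features, 1-based inclusive), and a
TSV truth table for simulated data.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import translate_cds


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """One gene locus: coordinates are 1-based inclusive genomic positions."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: str
    is_family: bool
    exon_lengths: tuple[int, ...]  # nucleotide lengths of CDS chunks per exon
    intron_lengths: tuple[int, ...] = ()

    @property
    def protein(self) -> str:
        return translate_cds(self.cds)

    @property
    def exon_count(self) -> int:
        return len(self.exon_lengths)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def exon_coords(self) -> list[tuple[int, int]]:
        """Genomic (start, end) of each exon, in order along the chromosome."""
        coords = []
        pos = self.start
        for i, ex in enumerate(self.exon_lengths):
            coords.append((pos, pos + ex - 1))
            pos += ex
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return coords


@dataclass
class GeneCatalog:
    """Genes of one species, kept in positional order within each chromosome."""

    species: str
    chromosomes: dict[str, list[GeneModel]] = field(default_factory=dict)

    # -- indexing ---------------------------------------------------------
    def genes(self) -> list[GeneModel]:
        out = []
        for chrom in self.chromosomes.values():
            out.extend(chrom)
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index()

    def _index(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes()}

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self._index()[gene_id]
        except KeyError:
            raise CatalogError(f"unknown gene id {gene_id!r}") from None

    def family_genes(self) -> list[GeneModel]:
        return [g for g in self.genes() if g.is_family]

    def locus_index(self, gene_id: str) -> tuple[str, int]:
        for chrom, genes in self.chromosomes.items():
            for i, g in enumerate(genes):
                if g.gene_id == gene_id:
                    return chrom, i
        raise CatalogError(f"unknown gene id {gene_id!r}")

    def validate(self) -> None:
        """Check coordinate sanity: ordered, non-overlapping, all >= 1."""
        for chrom, genes in self.chromosomes.items():
            prev_end = 0
            for g in genes:
                if g.start < 1 or g.end < g.start:
                    raise CatalogError(f"{g.gene_id}: bad span {g.start}-{g.end}")
                if g.start <= prev_end:
                    raise CatalogError(f"{g.gene_id}: overlaps previous gene on {chrom}")
                prev_end = g.end


class CatalogSet:
    """Lookup across several species' catalogs by gene id."""

    def __init__(self, catalogs: list[GeneCatalog] | dict[str, GeneCatalog]):
        if isinstance(catalogs, dict):
            catalogs = list(catalogs.values())
        self.catalogs: dict[str, GeneCatalog] = {c.species: c for c in catalogs}
        self._gene_index: dict[str, tuple[str, GeneModel]] = {}
        for c in catalogs:
            for g in c.genes():
                if g.gene_id in self._gene_index:
                    raise CatalogError(f"duplicate gene id across catalogs: {g.gene_id}")
                self._gene_index[g.gene_id] = (c.species, g)

    def species_of(self, gene_id: str) -> str:
        return self._gene_index[gene_id][0]

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self._gene_index[gene_id][1]
        except KeyError:
            raise CatalogError(f"unknown gene id {gene_id!r}") from None

    def catalog_of(self, gene_id: str) -> GeneCatalog:
        return self.catalogs[self.species_of(gene_id)]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def _gff3_lines(catalog: GeneCatalog) -> list[str]:
    lines = ["##gff-version 3"]
    for chrom in sorted(catalog.chromosomes):
        for g in catalog.chromosomes[chrom]:
            attrs = f"ID={g.gene_id};family={'1' if g.is_family else '0'}"
            lines.append(
                "\t".join(
                    [chrom, "duphist", "gene", str(g.start), str(g.end), ".", g.strand, ".", attrs]
                )
            )
            mrna_id = f"{g.gene_id}.1"
            lines.append(
                "\t".join(
                    [chrom, "duphist", "mRNA", str(g.start), str(g.end), ".", g.strand, ".",
                     f"ID={mrna_id};Parent={g.gene_id}"]
                )
            )
            for j, (s, e) in enumerate(g.exon_coords(), 1):
                for feat in ("exon", "CDS"):
                    lines.append(
                        "\t".join(
                            [chrom, "duphist", feat, str(s), str(e), ".", g.strand,
                             "0" if feat == "CDS" else ".",
                             f"ID={mrna_id}.{feat}{j};Parent={mrna_id}"]
                        )
                    )
    return lines


def export_catalog(catalog: GeneCatalog, out_prefix: str,
                   truth: pd.DataFrame | None = None) -> dict[str, str]:
    """Write CDS FASTA, protein FASTA, GFF3 and (optionally) a truth TSV.

    Returns a dict of the paths written. Output is deterministic given the
    catalog, so identical catalogs produce byte-identical files.
    """
    catalog.validate()
    os.makedirs(os.path.dirname(out_prefix) or ".", exist_ok=True)
    paths = {
        "cds": f"{out_prefix}.cds.fasta",
        "protein": f"{out_prefix}.protein.fasta",
        "gff3": f"{out_prefix}.gff3",
    }
    genes = catalog.genes()
    with open(paths["cds"], "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(g.cds), id=g.gene_id, description="") for g in genes), fh, "fasta"
        )
    with open(paths["protein"], "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(g.protein), id=g.gene_id, description="") for g in genes), fh, "fasta"
        )
    with open(paths["gff3"], "w") as fh:
        fh.write("\n".join(_gff3_lines(catalog)) + "\n")
    if truth is not None:
        paths["truth"] = f"{out_prefix}.truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def import_catalog(out_prefix: str, species: str) -> GeneCatalog:
    """Rebuild a catalog from files written by :func:`export_catalog`."""
    import gffutils

    cds = {r.id: str(r.seq) for r in SeqIO.parse(f"{out_prefix}.cds.fasta", "fasta")}
    with open(f"{out_prefix}.gff3") as fh:
        gff_text = fh.read()
    db = gffutils.create_db(
        io.StringIO(gff_text).getvalue(), dbfn=":memory:", from_string=True,
        merge_strategy="create_unique", keep_order=True,
    )
    per_chrom: dict[str, list[GeneModel]] = {}
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon")
        )
        exon_lengths = tuple(e - s + 1 for s, e in exons)
        introns = tuple(
            exons[i + 1][0] - exons[i][1] - 1 for i in range(len(exons) - 1)
        )
        gm = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            start=gene.start,
            end=gene.end,
            strand=gene.strand,
            cds=cds[gene.id],
            is_family=gene.attributes.get("family", ["0"])[0] == "1",
            exon_lengths=exon_lengths,
            intron_lengths=introns,
        )
        per_chrom.setdefault(gene.seqid, []).append(gm)
    for chrom in per_chrom:
        per_chrom[chrom].sort(key=lambda g: g.start)
    cat = GeneCatalog(species=species, chromosomes=dict(sorted(per_chrom.items())))
    cat.validate()
    return cat


def shift_downstream(genes: list[GeneModel], from_index: int, offset: int) -> list[GeneModel]:
    """Shift coordinates of genes[from_index:] by a constant offset."""
    out = list(genes[:from_index])
    for g in genes[from_index:]:
        out.append(replace(g, start=g.start + offset, end=g.end + offset))
    return out
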