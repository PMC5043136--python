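"""Synthetic genomes with planted duplication events and controlled divergence.

The simulator emulates the study design of gene-family duplication analyses:
multi-chromosome gene catalogs with a focal family embedded among background
genes, whole-genome/segmental duplications, tandem arrays, gene loss, and
codon-level divergence at controlled synonymous distance (Ks) and rate ratio
(omega = Ka/Ks). Every event is logged in a truth table so downstream callers
(homology, synteny, dating) can be scored against planted ground truth.

Divergence model
----------------
``evolve_cds_pair`` plants substitution events directly: the number of
synonymous events is Poisson with mean ``target_ks x S`` and the number of
nonsynonymous events Poisson with mean ``target_omega x target_ks x N``,
where S and N are the Nei-Gojobori synonymous/nonsynonymous site counts of
the input. Each event picks uniformly among the currently available single
nucleotide changes of its class; changes creating stop codons are never
available. The NG86 estimator with Jukes-Cantor correction is therefore an
approximately unbiased estimator of ``target_ks`` at moderate divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import CatalogError, GeneCatalog, GeneModel, shift_downstream
from .genetics import (
    NON_CHANGES,
    SENSE_CODONS,
    STOP_CODONS,
    SYN_CHANGES,
    SYNONYMOUS_SITES,
    SequenceError,
    codons_of,
)

TRUTH_COLUMNS = ["event_kind", "parent_gene", "child_gene", "target_ks", "target_omega", "era_label"]
_EVENT_KINDS = {"wgd", "segmental", "tandem", "loss"}


@dataclass(frozen=True)
class TruthRecord:
    event_kind: str
    parent_gene: str
    child_gene: str  # empty for loss
    target_ks: float
    target_omega: float
    era_label: str

    def __post_init__(self):
        if self.event_kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.event_kind!r}")
        if self.target_ks < 0:
            raise ValueError("target_ks must be >= 0")


def truth_frame(records: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=TRUTH_COLUMNS)


@dataclass
class SimConfig:
    """Shape of an ancestral genome; the seed fully determines the output."""

    n_chromosomes: int = 2
    genes_per_chromosome: int = 40
    family_founder_count: int = 2
    gene_length_codons: tuple[int, int] = (150, 250)
    intergenic_gap_bp: tuple[int, int] = (2000, 6000)
    exon_count_range: tuple[int, int] = (6, 9)
    intron_length_bp: tuple[int, int] = (80, 400)
    random_strand: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_chromosomes, self.genes_per_chromosome, self.family_founder_count) < 1:
            raise CatalogError("all counts must be >= 1")
        if self.gene_length_codons[0] < 110:
            # keeps every CDS > 300 bp so planted duplicates are callable
            raise CatalogError("minimum gene length must be >= 110 codons")
        if self.family_founder_count > self.n_chromosomes * self.genes_per_chromosome:
            raise CatalogError("more family founders than genes")


# ---------------------------------------------------------------------------
# sequence generation and divergence
# ---------------------------------------------------------------------------

def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS of n_codons total: ATG start, random sense body, one stop."""
    if n_codons < 3:
        raise SequenceError("need at least 3 codons")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = sorted(STOP_CODONS)[rng.integers(0, 3)]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def evolve_cds_pair(cds: str, target_ks: float, target_omega: float, seed) -> str:
    """Return a mutated copy of ``cds`` with planted Ks/omega (see module docs).

    Length is preserved, stop codons are never introduced, and a terminal
    stop codon (if present) is left untouched.
    """
    if target_ks < 0 or target_omega < 0:
        raise ValueError("target_ks and target_omega must be >= 0")
    rng = _as_rng(seed)
    cods = codons_of(cds)
    has_stop = bool(cods) and cods[-1] in STOP_CODONS
    body = cods[:-1] if has_stop else list(cods)
    if any(c in STOP_CODONS for c in body):
        raise SequenceError("internal stop codon in input CDS")
    s_sites = sum(SYNONYMOUS_SITES[c] for c in body)
    n_sites = 3 * len(body) - s_sites
    n_syn = rng.poisson(target_ks * s_sites)
    n_non = rng.poisson(target_omega * target_ks * n_sites)
    events = np.array(["s"] * n_syn + ["n"] * n_non)
    rng.shuffle(events)
    for kind in events:
        table = SYN_CHANGES if kind == "s" else NON_CHANGES
        counts = np.fromiter((len(table[c]) for c in body), dtype=np.int64, count=len(body))
        total = int(counts.sum())
        if total == 0:
            continue
        pick = rng.integers(0, total)
        idx = int(np.searchsorted(np.cumsum(counts), pick, side="right"))
        choices = table[body[idx]]
        _, new_codon = choices[pick - int(counts[:idx].sum())]
        body[idx] = new_codon
    return "".join(body) + (cods[-1] if has_stop else "")


# ---------------------------------------------------------------------------
# ancestral genome
# ---------------------------------------------------------------------------

def build_ancestral_genome(config: SimConfig, species: str = "anc") -> GeneCatalog:
    """Generate an ancestral catalog with family founders spread across chromosomes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_chromosomes * config.genes_per_chromosome
    # founders on distinct chromosomes where possible, at random loci
    founder_slots: set[tuple[int, int]] = set()
    for j in range(config.family_founder_count):
        chrom_i = j % config.n_chromosomes
        while True:
            slot = (chrom_i, int(rng.integers(0, config.genes_per_chromosome)))
            if slot not in founder_slots:
                founder_slots.add(slot)
                break
    chromosomes: dict[str, list[GeneModel]] = {}
    gid = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        genes: list[GeneModel] = []
        pos = 1
        for li in range(config.genes_per_chromosome):
            gid += 1
            n_codons = int(rng.integers(config.gene_length_codons[0],
                                        config.gene_length_codons[1] + 1))
            cds = random_cds(rng, n_codons)
            n_exons = int(rng.integers(config.exon_count_range[0],
                                       config.exon_count_range[1] + 1))
            exon_lengths = _split_lengths(len(cds), n_exons)
            introns = tuple(int(rng.integers(config.intron_length_bp[0],
                                             config.intron_length_bp[1] + 1))
                            for _ in range(n_exons - 1))
            gap = int(rng.integers(config.intergenic_gap_bp[0],
                                   config.intergenic_gap_bp[1] + 1))
            start = pos + gap
            end = start + len(cds) + sum(introns) - 1
            strand = "+" if not config.random_strand else ("+", "-")[int(rng.integers(0, 2))]
            genes.append(GeneModel(
                gene_id=f"{species}{gid:04d}", chrom=chrom, start=start, end=end,
                strand=strand, cds=cds, is_family=(ci, li) in founder_slots,
                exon_lengths=exon_lengths, intron_lengths=introns,
            ))
            pos = end
        chromosomes[chrom] = genes
    cat = GeneCatalog(species=species, chromosomes=chromosomes)
    cat.validate()
    assert len(cat) == n_total
    return cat


def _split_lengths(total: int, parts: int) -> tuple[int, ...]:
    base, rem = divmod(total, parts)
    return tuple(base + (1 if i < rem else 0) for i in range(parts))


# ---------------------------------------------------------------------------
# duplication events
# ---------------------------------------------------------------------------

def apply_wgd(catalog: GeneCatalog, target_ks: float, retention_rate: float,
              era_label: str, seed, target_omega: float = 0.2,
              ) -> tuple[GeneCatalog, list[TruthRecord]]:
    """Duplicate every chromosome; retain each duplicate gene independently.

    Retained duplicates are diverged from their parents at ``target_ks`` /
    ``target_omega`` and placed on a new chromosome preserving gene order and
    coordinates; dropped duplicates yield loss records.
    """
    if not 0 <= retention_rate <= 1:
        raise ValueError("retention_rate must be in [0, 1]")
    rng = _as_rng(seed)
    records: list[TruthRecord] = []
    new_chroms: dict[str, list[GeneModel]] = {}
    for chrom in sorted(catalog.chromosomes):
        dup_chrom = f"{chrom}_{era_label}"
        dup_genes: list[GeneModel] = []
        for g in catalog.chromosomes[chrom]:
            child_id = f"{g.gene_id}_{era_label}"
            if rng.random() < retention_rate:
                cds = evolve_cds_pair(g.cds, target_ks, target_omega, rng)
                dup_genes.append(replace(g, gene_id=child_id, chrom=dup_chrom, cds=cds))
                records.append(TruthRecord("wgd", g.gene_id, child_id,
                                           target_ks, target_omega, era_label))
            else:
                records.append(TruthRecord("loss", g.gene_id, "",
                                           target_ks, target_omega, era_label))
        if dup_genes:
            new_chroms[dup_chrom] = dup_genes
    out = GeneCatalog(species=catalog.species,
                      chromosomes={**{c: list(v) for c, v in catalog.chromosomes.items()},
                                   **new_chroms})
    out.validate()
    return out, records


def apply_tandem_array(catalog: GeneCatalog, gene_id: str, copies: int, gap_bp: int,
                       intervening_loci: int, target_ks: float, seed,
                       target_omega: float = 0.2, era_label: str = "tandem",
                       ) -> tuple[GeneCatalog, list[TruthRecord]]:
    """Insert ``copies`` diverged duplicates downstream of ``gene_id``.

    Consecutive family copies sit at nearest-boundary distance ``gap_bp``,
    with ``intervening_loci`` short background genes placed inside each gap.
    Downstream genes are shifted to keep coordinates consistent.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = _as_rng(seed)
    chrom, idx = catalog.locus_index(gene_id)
    parent = catalog.chromosomes[chrom][idx]
    inserted: list[GeneModel] = []
    records: list[TruthRecord] = []
    cursor = parent.end
    bg_counter = 0
    for c in range(1, copies + 1):
        # background genes inside the gap between consecutive family copies
        spacer = gap_bp // (intervening_loci + 1)
        for b in range(intervening_loci):
            bg_counter += 1
            cds = random_cds(rng, 120)
            start = cursor + spacer * (b + 1) - len(cds) // 2
            bg = GeneModel(
                gene_id=f"{gene_id}_bg{bg_counter}", chrom=chrom, start=start,
                end=start + len(cds) - 1, strand="+", cds=cds, is_family=False,
                exon_lengths=(len(cds),),
            )
            if bg.end >= cursor + gap_bp:
                raise CatalogError("gap_bp too small for requested intervening loci")
            inserted.append(bg)
        child_id = f"{gene_id}_{era_label}{c}"
        cds = evolve_cds_pair(parent.cds, target_ks, target_omega, rng)
        start = cursor + gap_bp
        child = replace(parent, gene_id=child_id, start=start,
                        end=start + parent.span - 1, cds=cds)
        inserted.append(child)
        records.append(TruthRecord("tandem", gene_id, child_id,
                                   target_ks, target_omega, era_label))
        cursor = child.end
    offset = cursor - parent.end
    genes = catalog.chromosomes[chrom]
    new_list = list(genes[: idx + 1]) + inserted + shift_downstream(genes, idx + 1, offset)[idx + 1:]
    chroms = {c: (new_list if c == chrom else list(v)) for c, v in catalog.chromosomes.items()}
    out = GeneCatalog(species=catalog.species, chromosomes=chroms)
    out.validate()
    return out, records


def apply_gene_loss(catalog: GeneCatalog, gene_ids: list[str],
                    era_label: str = "loss") -> tuple[GeneCatalog, list[TruthRecord]]:
    """Delete arbitrary genes (including ancestral originals) from a catalog."""
    drop = set(gene_ids)
    missing = drop - {g.gene_id for g in catalog.genes()}
    if missing:
        raise CatalogError(f"unknown gene ids: {sorted(missing)}")
    chroms = {c: [g for g in v if g.gene_id not in drop]
              for c, v in catalog.chromosomes.items()}
    records = [TruthRecord("loss", gid, "", 0.0, 0.0, era_label) for gid in sorted(drop)]
    return GeneCatalog(species=catalog.species, chromosomes=chroms), records


def insert_decoy(catalog: GeneCatalog, gene_id: str, target_ks: float, seed,
                 ) -> GeneCatalog:
    """Plant a non-family background gene partially similar to ``gene_id``.

    Stress-test helper: the decoy is a heavily diverged copy flagged as
    background, probing the homology caller's false-positive behavior.
    """
    rng = _as_rng(seed)
    chrom, idx = catalog.locus_index(gene_id)
    genes = catalog.chromosomes[chrom]
    src = genes[idx]
    last = genes[-1]
    cds = evolve_cds_pair(src.cds, target_ks, 1.0, rng)
    decoy = replace(src, gene_id=f"{gene_id}_decoy", is_family=False,
                    start=last.end + 3000, end=last.end + 3000 + src.span - 1, cds=cds)
    chroms = {c: (list(v) + [decoy] if c == chrom else list(v))
              for c, v in catalog.chromosomes.items()}
    return GeneCatalog(species=catalog.species, chromosomes=chroms)


def speciate(catalog: GeneCatalog, species: str, target_ks: float, seed,
             target_omega: float = 0.2) -> tuple[GeneCatalog, dict[str, str]]:
    """Derive a descendant species: every gene diverged at ``target_ks``.

    Returns the new catalog and the ancestor-gene -> descendant-gene map.
    Gene ids and chromosome names are prefixed with the species tag.
    """
    rng = _as_rng(seed)
    chroms: dict[str, list[GeneModel]] = {}
    mapping: dict[str, str] = {}
    for chrom in sorted(catalog.chromosomes):
        genes = []
        for g in catalog.chromosomes[chrom]:
            child_id = f"{species}_{g.gene_id}"
            cds = evolve_cds_pair(g.cds, target_ks, target_omega, rng)
            genes.append(replace(g, gene_id=child_id, chrom=f"{species}_{chrom}", cds=cds))
            mapping[g.gene_id] = child_id
        chroms[f"{species}_{chrom}"] = genes
    return GeneCatalog(species=species, chromosomes=chroms), mapping


# ---------------------------------------------------------------------------
# clade-level study simulation
# ---------------------------------------------------------------------------

@dataclass
class CladeSimulation:
    """A simulated multi-species clade plus the full event lineage.

    ``lineage`` holds one row per derived gene copy (columns: kind, parent,
    child, target_ks, era_label), including ``speciation`` rows that tie each
    species' genes back to the ancestral catalog.
    """

    catalogs: dict[str, GeneCatalog]
    lineage: pd.DataFrame
    truth: pd.DataFrame  # duplication/loss records only
    segmental_truth_pairs: pd.DataFrame  # species, gene_a, gene_b, era_label
    tandem_truth_pairs: pd.DataFrame
    params: dict = field(default_factory=dict)


def simulate_clade(seed: int, species: tuple[str, ...] = ("s1", "s2", "s3", "s4"),
                   n_chromosomes: int = 2, genes_per_chromosome: int = 30,
                   family_founder_count: int = 2,
                   gamma_ks: float = 1.5, gamma_retention: float = 0.8,
                   speciation_ks: float = 0.1,
                   recent_wgd_ks: float = 0.3, recent_retention: float = 0.8,
                   tandem_copies: int = 2, tandem_gap_bp: int = 12000,
                   tandem_ks: float = 0.05) -> CladeSimulation:
    """Simulate the study's clade design: one ancient duplication shared by all
    species, one recent WGD private to the first species, and one tandem array
    in the second species.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_chromosomes=n_chromosomes, genes_per_chromosome=genes_per_chromosome,
                    family_founder_count=family_founder_count,
                    seed=int(rng.integers(0, 2**31 - 1)))
    anc = build_ancestral_genome(cfg)
    anc, gamma_records = apply_wgd(anc, gamma_ks, gamma_retention, "gamma", rng)
    lineage_rows = [r.__dict__ for r in gamma_records]
    truth_records = list(gamma_records)

    catalogs: dict[str, GeneCatalog] = {}
    for sp in species:
        cat, mapping = speciate(anc, sp, speciation_ks, rng)
        catalogs[sp] = cat
        for parent, child in mapping.items():
            lineage_rows.append(dict(event_kind="speciation", parent_gene=parent,
                                     child_gene=child, target_ks=speciation_ks,
                                     target_omega=0.2, era_label=""))

    cat1, recent_records = apply_wgd(catalogs[species[0]], recent_wgd_ks,
                                     recent_retention, "recent", rng)
    catalogs[species[0]] = cat1
    truth_records.extend(recent_records)
    lineage_rows.extend(r.__dict__ for r in recent_records)

    fam2 = catalogs[species[1]].family_genes()[0].gene_id
    cat2, tandem_records = apply_tandem_array(
        catalogs[species[1]], fam2, copies=tandem_copies, gap_bp=tandem_gap_bp,
        intervening_loci=1, target_ks=tandem_ks, seed=rng)
    catalogs[species[1]] = cat2
    truth_records.extend(tandem_records)
    lineage_rows.extend(r.__dict__ for r in tandem_records)

    lineage = pd.DataFrame(lineage_rows, columns=TRUTH_COLUMNS)
    truth = truth_frame(truth_records)

    catsets = {sp: {g.gene_id for g in c.genes()} for sp, c in catalogs.items()}
    fam = {sp: {g.gene_id for g in c.family_genes()} for sp, c in catalogs.items()}
    seg_rows = []
    # ancient event: within-species descendants of each retained gamma pair
    for r in gamma_records:
        if r.event_kind != "wgd":
            continue
        for sp in species:
            a, b = f"{sp}_{r.parent_gene}", f"{sp}_{r.child_gene}"
            if a in fam[sp] and b in fam[sp]:
                seg_rows.append(dict(species=sp, gene_a=a, gene_b=b, era_label="gamma"))
    for r in recent_records:
        if r.event_kind == "wgd" and r.parent_gene in fam[species[0]] \
                and r.child_gene in fam[species[0]]:
            seg_rows.append(dict(species=species[0], gene_a=r.parent_gene,
                                 gene_b=r.child_gene, era_label="recent"))
    # recent duplicates of gamma copies also form gamma-age pairs
    recent_map = {r.parent_gene: r.child_gene for r in recent_records if r.event_kind == "wgd"}
    for r in gamma_records:
        if r.event_kind != "wgd":
            continue
        sp = species[0]
        a, b = f"{sp}_{r.parent_gene}", f"{sp}_{r.child_gene}"
        if not (a in fam[sp] and b in fam[sp]):
            continue
        for x, y in ((recent_map.get(a), b), (a, recent_map.get(b)),
                     (recent_map.get(a), recent_map.get(b))):
            if x and y and x in catsets[sp] and y in catsets[sp] \
                    and x in fam[sp] and y in fam[sp]:
                seg_rows.append(dict(species=sp, gene_a=x, gene_b=y, era_label="gamma"))
    seg = pd.DataFrame(seg_rows, columns=["species", "gene_a", "gene_b", "era_label"])

    td_rows = [dict(species=species[1], gene_a=r.parent_gene, gene_b=r.child_gene)
               for r in tandem_records]
    # consecutive tandem copies are also tandem pairs of each other
    children = [r.child_gene for r in tandem_records]
    for i in range(len(children)):
        for j in range(i + 1, len(children)):
            td_rows.append(dict(species=species[1], gene_a=children[i], gene_b=children[j]))
    td = pd.DataFrame(td_rows, columns=["species", "gene_a", "gene_b"])

    params = dict(seed=seed, species=list(species), gamma_ks=gamma_ks,
                  speciation_ks=speciation_ks, recent_wgd_ks=recent_wgd_ks,
                  gamma_retention=gamma_retention, recent_retention=recent_retention)
    return CladeSimulation(catalogs=catalogs, lineage=lineage, truth=truth,
                           segmental_truth_pairs=seg, tandem_truth_pairs=td, params=params)


def expected_pair_era(lineage: pd.DataFrame, gene_a: str, gene_b: str) -> str | None:
    """Era label of the oldest duplication event separating two genes.

    Walks the copy tree implied by the lineage table: the path between the
    two genes through their lowest common ancestor is collected, and among
    its duplication edges (speciation edges ignored) the one with the largest
    planted Ks — i.e. the oldest — gives the label. Returns None for pure
    orthologs (no duplication on the path).
    """
    parent_of: dict[str, tuple[str, str, float, str]] = {}
    for row in lineage.itertuples():
        if row.event_kind == "loss" or not row.child_gene:
            continue
        parent_of[row.child_gene] = (row.parent_gene, row.event_kind,
                                     row.target_ks, row.era_label)

    def chain(g: str) -> list[str]:
        out = [g]
        while out[-1] in parent_of:
            out.append(parent_of[out[-1]][0])
        return out

    ca, cb = chain(gene_a), chain(gene_b)
    seen = {g: i for i, g in enumerate(ca)}
    lca = next((g for g in cb if g in seen), None)
    if lca is None:
        return None
    path = ca[: seen[lca]] + cb[: cb.index(lca)]
    best = None
    for g in path:
        parent, kind, ks, era = parent_of[g]
        if kind == "speciation":
            continue
        if best is None or ks > best[0]:
            best = (ks, era)
    return best[1] if best else None
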