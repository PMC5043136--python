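"""End-to-end orchestration: simulate/load -> homology -> Ka/Ks -> synteny ->
dating -> retention -> phylogeny, with TSV intermediates and a run manifest.

Each stage writes its table under the output directory; with ``resume=True``
stages whose outputs exist are skipped on the expensive recompute path where
that is safe (catalogs and homology hits), yielding identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import dating, homology, phylo, report, synteny
from .catalog import CatalogSet, GeneCatalog, export_catalog, import_catalog
from .dating import Era, EraConfig
from .kaks import KaKsResult, kaks_for_cds_pair
from .simulate import CladeSimulation, simulate_clade

log = logging.getLogger("duphist")


class PipelineError(RuntimeError):
    pass


@dataclass
class SpeciesInput:
    name: str
    prefix: str  # file prefix as written by export_catalog


@dataclass
class PipelineConfig:
    outdir: str = "duphist_out"
    seed: int = 0
    species: list[SpeciesInput] | None = None  # None -> simulate a clade
    clade_params: dict = field(default_factory=dict)
    min_identity: float = 40.0
    min_length: int = 300
    window: int = 50
    min_flank_matches: int = 3
    tandem_kb: float = 60.0
    tandem_loci: int = 5
    bootstrap_replicates: int = 100
    era_config: EraConfig | None = None
    resume: bool = False

    def validate(self) -> None:
        if not (0 < self.min_identity <= 100):
            raise PipelineError("identity threshold must be in (0, 100]")
        if min(self.min_length, self.window, self.min_flank_matches) < 1 \
                or self.tandem_kb <= 0 or self.tandem_loci < 0:
            raise PipelineError("thresholds must be positive")
        if self.species is not None:
            names = [s.name for s in self.species]
            if len(names) != len(set(names)):
                raise PipelineError("species names must be unique")

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "era_config"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:12]


def _simulation_era_config(sim: CladeSimulation) -> EraConfig:
    """Era intervals and slot multiplicities implied by the clade design."""
    p = sim.params
    # the ancient band must absorb compounded divergence (event + speciation
    # + any later private WGD on both copies) and JC noise near saturation
    recent = Era("recent", p["recent_wgd_ks"], 0.05, 0.8)
    gamma = Era("gamma", p["gamma_ks"] + 2 * p["speciation_ks"], 1.05, 3.5)
    eras = {}
    slots = {}
    for i, sp in enumerate(p["species"]):
        eras[sp] = [recent, gamma] if i == 0 else [gamma]
        slots[sp] = 4 if i == 0 else 2
    return EraConfig(eras=eras, slots=slots)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the report bundle.

    The bundle maps stage names to in-memory results; every table is also
    written as TSV under ``config.outdir``.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    t0 = time.time()
    log.info("duphist run: seed=%s config=%s", config.seed, config.digest())
    for key in ("min_identity", "min_length", "window", "min_flank_matches",
                "tandem_kb", "tandem_loci"):
        log.info("threshold %s = %s", key, getattr(config, key))

    # --- stage: catalogs ---------------------------------------------------
    sim: CladeSimulation | None = None
    if config.species is None:
        sim = simulate_clade(seed=config.seed, **config.clade_params)
        catalogs = list(sim.catalogs.values())
        for sp, cat in sim.catalogs.items():
            export_catalog(cat, os.path.join(config.outdir, sp))
        sim.truth.to_csv(os.path.join(config.outdir, "truth.tsv"), sep="\t", index=False)
    else:
        try:
            catalogs = [import_catalog(s.prefix, s.name) for s in config.species]
        except FileNotFoundError as exc:
            raise PipelineError(f"stage catalogs: missing input {exc}") from exc
    cats = CatalogSet(catalogs)

    # --- stage: homology ---------------------------------------------------
    hits_path = os.path.join(config.outdir, "hits.tsv")
    if config.resume and os.path.exists(hits_path):
        hdf = pd.read_csv(hits_path, sep="\t")
        hits = [homology.HomologyHit(**row) for row in hdf.to_dict("records")]
    else:
        hits = homology.all_vs_all(catalogs)
        pd.DataFrame([h.__dict__ for h in hits]).to_csv(hits_path, sep="\t", index=False)
    log.info("homology: %d hits", len(hits))

    species_names = sorted(cats.catalogs)
    within = {sp: [] for sp in species_names}
    for h in hits:
        sa, sb = cats.species_of(h.query), cats.species_of(h.subject)
        if sa == sb:
            within[sa].append(h)
    paralogs = []
    for sp in species_names:
        paralogs.extend(homology.call_paralogs(
            within[sp], cats, config.min_identity, config.min_length))
    orthologs = []
    for i, sa in enumerate(species_names):
        for sb in species_names[i + 1 :]:
            ab, ba = homology.cross_species_hits(hits, cats, sa, sb)
            orthologs.extend(homology.call_orthologs(ab, ba, cats, config.min_length))
    _pairs_tsv(paralogs, os.path.join(config.outdir, "paralogs.tsv"))
    _pairs_tsv(orthologs, os.path.join(config.outdir, "orthologs.tsv"))

    # --- stage: synteny ----------------------------------------------------
    graph = synteny.build_homology_graph(hits)
    blocks = []
    for sp in species_names:
        blocks.extend(synteny.intra_species_synteny(
            cats.catalogs[sp], graph, config.window, config.min_flank_matches))
    for i, sa in enumerate(species_names):
        for sb in species_names[i + 1 :]:
            blocks.extend(synteny.cross_species_synteny(
                cats.catalogs[sa], cats.catalogs[sb], graph,
                config.window, config.min_flank_matches))
    nblocks = []
    for sp in species_names:
        nblocks.extend(synteny.subfunctionalized_partners(
            cats.catalogs[sp], graph, config.window, config.min_flank_matches))
    clusters = {sp: synteny.tandem_clusters(
        cats.catalogs[sp], max_distance_bp=int(config.tandem_kb * 1000),
        max_intervening=config.tandem_loci) for sp in species_names}
    classification = synteny.classify_family_pairs(blocks, cats)
    log.info("synteny: %d blocks, %d tandem clusters", len(blocks),
             sum(len(v) for v in clusters.values()))

    # --- stage: kaks -------------------------------------------------------
    kaks_table: dict[tuple[str, str], KaKsResult] = {}

    def ks_of(a: str, b: str) -> KaKsResult:
        key = tuple(sorted((a, b)))
        if key not in kaks_table:
            kaks_table[key] = kaks_for_cds_pair(cats.get(key[0]).cds, cats.get(key[1]).cds)
        return kaks_table[key]

    for p in paralogs + orthologs:
        ks_of(p.gene_a, p.gene_b)
    for blk in blocks:
        ks_of(*blk.anchors)
        for a, b in blk.flank_matches:
            ks_of(a, b)
    _kaks_tsv(kaks_table, os.path.join(config.outdir, "kaks.tsv"))

    # --- stage: dating + retention ------------------------------------------
    era_config = config.era_config
    if era_config is None:
        era_config = _simulation_era_config(sim) if sim is not None \
            else dating.default_rosid_config()
    dating.date_blocks(blocks, kaks_table, era_config)
    groups = synteny.ancestral_groups(blocks, cats)
    matrix = dating.build_retention_matrix(groups, blocks + nblocks, cats, era_config)
    benchmark = species_names[-1]
    multiplicity = dating.expected_multiplicity_check(matrix, era_config, benchmark)
    matrix.to_frame().to_csv(os.path.join(config.outdir, "retention_matrix.tsv"), sep="\t")
    multiplicity.to_csv(os.path.join(config.outdir, "multiplicity.tsv"),
                        sep="\t", index=False)

    # --- stage: phylo --------------------------------------------------------
    family_proteins = {g.gene_id: g.protein
                       for cat in catalogs for g in cat.family_genes()}
    tree = None
    if len(family_proteins) >= 3:
        tree = phylo.bootstrap_support(family_proteins,
                                       n_replicates=config.bootstrap_replicates,
                                       seed=config.seed)
        with open(os.path.join(config.outdir, "family_tree.nwk"), "w") as fh:
            fh.write(tree.newick(with_support=True) + "\n")

    # --- stage: report -------------------------------------------------------
    bundle = dict(
        catalogs=cats, hits=hits, paralogs=paralogs, orthologs=orthologs,
        kaks_table=kaks_table, blocks=blocks, n_blocks=nblocks, groups=groups,
        tandem_clusters=clusters, classification=classification,
        retention_matrix=matrix, multiplicity=multiplicity, tree=tree,
        era_config=era_config, simulation=sim,
    )
    tables = format_results_tables(bundle, config.outdir)
    bundle["tables"] = tables
    manifest = dict(seed=config.seed, config_digest=config.digest(),
                    n_genes=sum(len(c) for c in catalogs),
                    n_hits=len(hits), n_paralog_pairs=len(paralogs),
                    n_ortholog_pairs=len(orthologs), n_blocks=len(blocks),
                    runtime_s=round(time.time() - t0, 2))
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("done in %.1fs", time.time() - t0)
    return bundle


def format_results_tables(bundle: dict, outdir: str | None = None) -> dict[str, pd.DataFrame]:
    """Publication-style tables from a pipeline bundle (inventory, dated pairs,
    synteny-quality matrix, paralog percentages)."""
    cats: CatalogSet = bundle["catalogs"]
    catalogs = list(cats.catalogs.values())
    tables = {
        "inventory": report.gene_inventory(catalogs),
        "dated_pairs": report.dated_pairs_table(bundle["blocks"], bundle["kaks_table"]),
        "quality_matrix": report.synteny_quality_matrix(bundle["blocks"]),
        "paralog_percentages": report.paralog_percentages(bundle["paralogs"], catalogs),
    }
    if outdir:
        for name, tbl in tables.items():
            tbl.to_csv(os.path.join(outdir, f"table_{name}.tsv"), sep="\t",
                       index=name == "quality_matrix", na_rep="")
    return tables


def _pairs_tsv(pairs, path: str) -> None:
    pd.DataFrame(
        [dict(gene_a=p.gene_a, gene_b=p.gene_b, species_a=p.species_a,
              species_b=p.species_b,
              identity=p.evidence[0].identity if p.evidence else None,
              aligned_length=p.evidence[0].aligned_length if p.evidence else None)
         for p in pairs],
        columns=["gene_a", "gene_b", "species_a", "species_b", "identity", "aligned_length"],
    ).to_csv(path, sep="\t", index=False)


def _kaks_tsv(table: dict[tuple[str, str], KaKsResult], path: str) -> None:
    pd.DataFrame(
        [dict(gene_a=a, gene_b=b, ka=r.Ka, ks=r.Ks, omega=r.omega, regime=r.regime)
         for (a, b), r in sorted(table.items())],
        columns=["gene_a", "gene_b", "ka", "ks", "omega", "regime"],
    ).to_csv(path, sep="\t", index=False)
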