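"""Simulator contracts: catalog shape, determinism, divergence calibration,
event bookkeeping, and file round-trips."""

import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq

from duphist.catalog import CatalogError, export_catalog, import_catalog
from duphist.genetics import STOP_CODONS, codons_of
from duphist.kaks import CodonAlignment, compute_kaks
from duphist.simulate import (
    SimConfig,
    apply_gene_loss,
    apply_tandem_array,
    apply_wgd,
    build_ancestral_genome,
    evolve_cds_pair,
    expected_pair_era,
    random_cds,
    simulate_clade,
    speciate,
)
from duphist.synteny import tandem_test


def ng86_pair(cds_a: str, cds_b: str):
    """Direct NG86 on two equal-length CDSs (terminal stops stripped)."""
    ca = [c for c in codons_of(cds_a) if c not in STOP_CODONS]
    cb = [c for c in codons_of(cds_b) if c not in STOP_CODONS]
    return compute_kaks(CodonAlignment(tuple(ca), tuple(cb)))


class TestBuildAncestralGenome:
    def test_counts_forced_by_config(self):
        cat = build_ancestral_genome(
            SimConfig(n_chromosomes=1, genes_per_chromosome=10,
                      family_founder_count=1, seed=7))
        assert len(cat) == 10
        assert len(cat.family_genes()) == 1

    def test_all_cds_translate_cleanly(self):
        cat = build_ancestral_genome(
            SimConfig(n_chromosomes=3, genes_per_chromosome=200,
                      family_founder_count=4, seed=1))
        assert len(cat) == 600
        for g in cat.genes():
            # independent oracle: Biopython translation under the standard code
            prot = str(Seq(g.cds).translate())
            assert prot.endswith("*") and "*" not in prot[:-1]
            assert prot.startswith("M")
            assert g.protein == prot[:-1]

    def test_founders_on_distinct_chromosomes(self):
        cat = build_ancestral_genome(
            SimConfig(n_chromosomes=3, genes_per_chromosome=10,
                      family_founder_count=3, seed=2))
        chroms = {g.chrom for g in cat.family_genes()}
        assert len(chroms) == 3

    def test_coordinates_ordered_nonoverlapping(self, medium_catalog):
        for genes in medium_catalog.chromosomes.values():
            prev_end = 0
            for g in genes:
                assert g.start > prev_end
                assert g.end >= g.start >= 1
                prev_end = g.end

    @pytest.mark.parametrize("bad", [
        dict(family_founder_count=0),
        dict(n_chromosomes=0),
        dict(family_founder_count=100, n_chromosomes=1, genes_per_chromosome=10),
        dict(gene_length_codons=(50, 100)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(CatalogError):
            build_ancestral_genome(SimConfig(**bad))

    def test_determinism_byte_identical_files(self, tmp_path):
        cfg = SimConfig(n_chromosomes=1, genes_per_chromosome=10,
                        family_founder_count=1, seed=7)
        p1 = export_catalog(build_ancestral_genome(cfg), str(tmp_path / "a" / "run"))
        p2 = export_catalog(build_ancestral_genome(cfg), str(tmp_path / "b" / "run"))
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key


class TestEvolveCdsPair:
    def test_zero_divergence_is_identity(self, rng):
        cds = random_cds(rng, 200)
        assert evolve_cds_pair(cds, 0.0, 0.2, 1) == cds

    def test_length_and_stops_preserved(self, rng):
        cds = random_cds(rng, 300)
        out = evolve_cds_pair(cds, 1.5, 0.5, 2)
        assert len(out) == len(cds)
        cods = codons_of(out)
        assert cods[-1] in STOP_CODONS
        assert not any(c in STOP_CODONS for c in cods[:-1])

    def test_ks_calibration(self, rng):
        """Mean NG86 Ks over replicates tracks the target within 3 SE."""
        cds = random_cds(rng, 1000)
        est = [ng86_pair(cds, evolve_cds_pair(cds, 0.3, 0.2, s)).Ks
               for s in range(40)]
        assert 0.27 <= np.mean(est) <= 0.33

    def test_neutral_omega_calibration(self, rng):
        cds = random_cds(rng, 1000)
        est = [ng86_pair(cds, evolve_cds_pair(cds, 0.3, 1.0, s)).omega
               for s in range(30)]
        assert 0.9 <= np.mean(est) <= 1.1

    def test_invalid_codon_rejected(self):
        from duphist.genetics import SequenceError
        with pytest.raises(SequenceError):
            evolve_cds_pair("ATGTAAAAATGA", 0.1, 0.2, 1)  # internal stop


class TestApplyWgd:
    def test_full_retention_zero_ks_doubles(self, small_catalog):
        out, records = apply_wgd(small_catalog, 0.0, 1.0, "e1", seed=3)
        assert len(out) == 2 * len(small_catalog)
        by_id = {g.gene_id: g for g in out.genes()}
        for r in records:
            assert r.event_kind == "wgd"
            assert by_id[r.child_gene].cds == by_id[r.parent_gene].cds

    def test_zero_retention_only_losses(self, small_catalog):
        out, records = apply_wgd(small_catalog, 0.1, 0.0, "e1", seed=3)
        assert len(out) == len(small_catalog)
        assert {r.event_kind for r in records} == {"loss"}

    def test_retention_is_binomial(self, medium_catalog):
        n = len(medium_catalog)
        retained = []
        for s in range(30):
            _, records = apply_wgd(medium_catalog, 0.0, 0.5, "e1", seed=s)
            retained.append(sum(r.event_kind == "wgd" for r in records))
        se_mean = np.sqrt(n * 0.25 / 30)
        assert abs(np.mean(retained) - n * 0.5) <= 3 * se_mean + 1

    def test_event_conservation(self, small_catalog):
        out, records = apply_wgd(small_catalog, 0.2, 0.7, "e1", seed=9)
        n_retained = sum(r.event_kind == "wgd" for r in records)
        assert len(out) == len(small_catalog) + n_retained
        # ancestral originals never removed
        orig = {g.gene_id for g in small_catalog.genes()}
        assert orig <= {g.gene_id for g in out.genes()}


class TestApplyTandemArray:
    def test_adds_family_copies_on_same_chromosome(self, small_catalog):
        fam = small_catalog.family_genes()[0]
        out, records = apply_tandem_array(small_catalog, fam.gene_id, copies=3,
                                          gap_bp=12000, intervening_loci=0,
                                          target_ks=0.05, seed=1)
        assert len(out.family_genes()) == len(small_catalog.family_genes()) + 3
        chrom, _ = out.locus_index(fam.gene_id)
        for r in records:
            assert out.locus_index(r.child_gene)[0] == chrom
        out.validate()

    def test_close_copy_passes_tandem_rule(self, small_catalog):
        fam = small_catalog.family_genes()[0]
        out, records = apply_tandem_array(small_catalog, fam.gene_id, copies=1,
                                          gap_bp=12000, intervening_loci=0,
                                          target_ks=0.05, seed=1)
        assert tandem_test(fam.gene_id, records[0].child_gene, out)

    def test_distant_copy_fails_tandem_rule(self, small_catalog):
        fam = small_catalog.family_genes()[0]
        out, records = apply_tandem_array(small_catalog, fam.gene_id, copies=1,
                                          gap_bp=61000, intervening_loci=0,
                                          target_ks=0.05, seed=1)
        assert not tandem_test(fam.gene_id, records[0].child_gene, out)

    def test_unknown_gene_rejected(self, small_catalog):
        with pytest.raises(CatalogError):
            apply_tandem_array(small_catalog, "nope", 1, 12000, 0, 0.1, 1)


class TestExportImport:
    def test_round_trip_equality(self, tmp_path, small_catalog):
        prefix = str(tmp_path / "cat")
        export_catalog(small_catalog, prefix)
        back = import_catalog(prefix, small_catalog.species)
        assert {g.gene_id: g for g in back.genes()} == \
               {g.gene_id: g for g in small_catalog.genes()}

    def test_gff3_feature_counts(self, tmp_path, small_catalog):
        prefix = str(tmp_path / "cat")
        paths = export_catalog(small_catalog, prefix)
        lines = [l.split("\t") for l in open(paths["gff3"]) if not l.startswith("#")]
        genes = [l for l in lines if l[2] == "gene"]
        exons = [l for l in lines if l[2] == "exon"]
        assert len(genes) == len(small_catalog)
        assert len(exons) == sum(g.exon_count for g in small_catalog.genes())
        # coordinates strictly increasing within each chromosome
        starts = {}
        for l in genes:
            starts.setdefault(l[0], []).append(int(l[3]))
        for v in starts.values():
            assert v == sorted(v) and len(set(v)) == len(v)


class TestGeneLossAndLineage:
    def test_loss_targets_ancestors_when_asked(self, small_catalog):
        victim = small_catalog.genes()[0].gene_id
        out, records = apply_gene_loss(small_catalog, [victim])
        assert victim not in out
        assert records[0].event_kind == "loss"

    def test_expected_pair_era_walks_copy_tree(self):
        sim = simulate_clade(seed=1, genes_per_chromosome=12)
        # a planted recent pair has era "recent", a gamma pair "gamma"
        for row in sim.segmental_truth_pairs.itertuples():
            assert expected_pair_era(sim.lineage, row.gene_a, row.gene_b) == row.era_label
        # orthologs (same ancestor, different species) have no duplication era
        s3 = sim.catalogs["s3"].genes()[0].gene_id
        s4 = "s4" + s3[2:]
        assert expected_pair_era(sim.lineage, s3, s4) is None


class TestSpeciate:
    def test_mapping_covers_catalog(self, small_catalog):
        cat, mapping = speciate(small_catalog, "x", 0.3, seed=1)
        assert len(cat) == len(small_catalog)
        assert set(mapping.values()) == {g.gene_id for g in cat.genes()}

    def test_divergence_near_target(self, medium_catalog):
        cat, mapping = speciate(medium_catalog, "x", 0.4, seed=2)
        orig = {g.gene_id: g.cds for g in medium_catalog.genes()}
        new = {g.gene_id: g.cds for g in cat.genes()}
        ks = [ng86_pair(orig[p], new[c]).Ks for p, c in mapping.items()]
        assert 0.34 <= np.mean(ks) <= 0.46
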