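"""Generator contracts: determinism, invariants, limiting cases."""

import math

import numpy as np
import pandas as pd
import pytest

from mkscan.codon_model import gene_site_totals
from mkscan.inter_divergence import compute_pair_divergence, translate_cds
from mkscan.seqio import read_gene_models, read_similarity_hits, read_vcf
from mkscan.synthetic_data import (
    SimulationConfig,
    assign_classes,
    evolve_divergence,
    evolve_polymorphism,
    simulate_ancestral_genes,
    simulate_dataset,
)


def small_config(**overrides):
    defaults = dict(n_genes=20, n_accessions=6, codons_min=50, codons_max=80, seed=9)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_fraction_sum_capped(self):
        cfg = small_config(frac_mqtg_only=0.6, frac_mqtg_cnv=0.5)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_negative_rate_rejected(self):
        cfg = small_config(theta_syn=-0.1)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_neutral_constructor_sets_all_omegas_to_one(self):
        cfg = SimulationConfig.neutral(n_genes=5)
        assert set(cfg.omega_div.values()) == {1.0}
        assert set(cfg.omega_poly.values()) == {1.0}


class TestAncestralGenes:
    def test_genes_satisfy_model_invariants(self):
        cfg = small_config()
        genes, genome, _ = simulate_ancestral_genes(cfg)
        assert len(genes) == cfg.n_genes
        for gene in genes:
            gene.validate()  # frame, no internal stops, interval law
            assert gene.cds_sequence.startswith("ATG")

    def test_both_strands_and_splicing_occur(self):
        genes, _, _ = simulate_ancestral_genes(small_config(n_genes=40))
        assert {g.strand for g in genes} == {"+", "-"}
        assert any(len(g.cds_intervals) == 2 for g in genes)

    def test_emitted_files_reparse_without_rejection(self, tmp_path):
        cfg = small_config()
        paths = simulate_dataset(cfg, tmp_path)
        genes, rejected = read_gene_models(paths["gff"], paths["genome"])
        assert rejected == []
        assert len(genes) == cfg.n_genes
        # genome slices reverse-complement back to the emitted CDS
        from Bio import SeqIO

        cds = {r.id: str(r.seq) for r in SeqIO.parse(str(paths["cds_a"]), "fasta")}
        for gene in genes:
            assert gene.cds_sequence == cds[gene.gene_id]

    def test_fixed_seed_reproduces_files_byte_identically(self, tmp_path):
        cfg = small_config()
        paths1 = simulate_dataset(cfg, tmp_path / "run1")
        paths2 = simulate_dataset(small_config(), tmp_path / "run2")
        for key in ("genome", "gff", "cds_b", "vcf", "hits_ab", "truth"):
            assert paths1[key].read_bytes() == paths2[key].read_bytes()


class TestEvolveDivergence:
    def test_zero_divergence_leaves_species_identical(self):
        cfg = small_config(divergence_ks_target=0.0)
        rng = np.random.default_rng(cfg.seed)
        classes = assign_classes(cfg, rng)
        genes, _, _ = simulate_ancestral_genes(cfg, rng)
        species_b, truth = evolve_divergence(genes, classes, cfg, rng)
        for gene in genes:
            assert species_b[gene.gene_id] == gene.cds_sequence
        assert all(t["dn_true"] == t["ds_true"] == 0 for t in truth)

    def test_omega_zero_class_shows_no_nonsynonymous_change(self):
        cfg = small_config(frac_mqtg_cnv=1.0, frac_mqtg_only=0.0, frac_cnv_only=0.0)
        cfg.omega_div["mqtg_cnv"] = 0.0
        rng = np.random.default_rng(cfg.seed)
        classes = assign_classes(cfg, rng)
        genes, _, _ = simulate_ancestral_genes(cfg, rng)
        species_b, truth = evolve_divergence(genes, classes, cfg, rng)
        assert all(t["dn_true"] == 0 for t in truth)
        for gene in genes:
            assert translate_cds(species_b[gene.gene_id]) == translate_cds(gene.cds_sequence)

    def test_neutral_rates_calibrated_to_ks_target(self):
        # with omega = 1 the realized Ds/S should track the Ks target and
        # Dn/N should match it (stop-exclusion affects both estimates alike)
        cfg = SimulationConfig.neutral(
            n_genes=60, codons_min=200, codons_max=300, seed=13
        )
        rng = np.random.default_rng(cfg.seed)
        classes = assign_classes(cfg, rng)
        genes, _, _ = simulate_ancestral_genes(cfg, rng)
        species_b, _ = evolve_divergence(genes, classes, cfg, rng)
        ratios = []
        for gene in genes:
            d = compute_pair_divergence(gene.cds_sequence, species_b[gene.gene_id])
            if not math.isnan(d.ka_ks):
                ratios.append(d.ka_ks)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


class TestEvolvePolymorphism:
    def test_zero_theta_gives_empty_vcf_body(self, tmp_path):
        cfg = small_config(theta_syn=0.0)
        paths = simulate_dataset(cfg, tmp_path)
        records, _ = read_vcf(paths["vcf"])
        assert records == []

    def test_vcf_round_trips_with_carrier_sets(self, tmp_path):
        cfg = small_config()
        paths = simulate_dataset(cfg, tmp_path)
        records, skipped = read_vcf(paths["vcf"])
        assert not any(skipped.values())
        manifest = paths["manifest"].read_text()
        assert f'"n_vcf_records": {len(records)}' in manifest
        assert all(1 <= len(r.accession_presence) <= cfg.n_accessions for r in records)

    def test_planted_counts_recorded_in_truth(self, tmp_path):
        cfg = small_config()
        paths = simulate_dataset(cfg, tmp_path)
        truth = pd.read_csv(paths["truth"], sep="\t")
        records, _ = read_vcf(paths["vcf"])
        assert truth[["pn_true", "ps_true"]].to_numpy().sum() == len(records)


class TestLabelsAndHits:
    def test_class_fractions_respected(self):
        cfg = SimulationConfig(n_genes=200, seed=1)
        classes = assign_classes(cfg, np.random.default_rng(1))
        counts = pd.Series(classes).value_counts()
        assert counts["mqtg_only"] == round(0.30 * 200)
        assert counts["mqtg_cnv"] == round(0.35 * 200)

    def test_labels_match_truth_classes(self, tmp_path):
        paths = simulate_dataset(small_config(), tmp_path)
        labels = pd.read_csv(paths["labels"], sep="\t").set_index("gene_id")
        truth = pd.read_csv(paths["truth"], sep="\t").set_index("gene_id")
        for gene_id, row in truth.iterrows():
            assert labels.loc[gene_id, "is_mqtg"] == int(row["gene_class"] in ("mqtg_only", "mqtg_cnv"))
            assert labels.loc[gene_id, "has_cnv"] == int(row["gene_class"] in ("cnv_only", "mqtg_cnv"))

    def test_hit_tables_recover_true_pairing(self, tmp_path):
        from mkscan.inter_divergence import reciprocal_best_hits

        from Bio import SeqIO

        cfg = small_config()
        paths = simulate_dataset(cfg, tmp_path)
        lengths_a = {r.id: len(r.seq) for r in SeqIO.parse(str(paths["protein_a"]), "fasta")}
        lengths_b = {r.id: len(r.seq) for r in SeqIO.parse(str(paths["protein_b"]), "fasta")}
        hits_ab = read_similarity_hits(paths["hits_ab"], lengths_a)
        hits_ba = read_similarity_hits(paths["hits_ba"], lengths_b)
        pairs = reciprocal_best_hits(hits_ab, hits_ba)
        assert len(pairs) == cfg.n_genes
        assert all(p.gene_b == p.gene_a.replace("AT", "AL") for p in pairs)
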