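"""Tests for the synthetic data generator: determinism, planted truth,
count moments, repertoire reads, ATAC structure and annotation."""

import numpy as np
import pandas as pd
import pytest

from mbcomics import synth


class TestExpressionGenerator:
    def test_same_seed_is_bit_identical_and_seeds_differ(self, small_config):
        cm1, t1 = synth.generate_expression(small_config)
        cm2, t2 = synth.generate_expression(small_config)
        assert cm1.counts.equals(cm2.counts)
        assert t1.equals(t2)
        other = synth.GeneratorConfig(
            n_genes=small_config.n_genes, n_mirnas=small_config.n_mirnas,
            n_lncrnas=small_config.n_lncrnas, n_peaks=small_config.n_peaks,
            seed=small_config.seed + 1,
        )
        cm3, _ = synth.generate_expression(other)
        assert not cm1.counts.equals(cm3.counts)

    def test_null_plan_gives_truth_without_planted_effects(self, small_config):
        plan = synth.SignaturePlan()
        cm, truth = synth.generate_expression(small_config, plan)
        assert (truth["role"] == "null").all()
        eff_cols = [c for c in truth.columns if c.startswith("effect_")]
        assert (truth[eff_cols] == 0).all().all()

    def test_default_plan_places_17_up_7_down_and_partitions_features(self):
        plan = synth.default_signature_plan()
        assert len(plan.up_genes) == 17
        assert len(plan.down_genes) == 7
        cfg = synth.GeneratorConfig(n_genes=1500, seed=3)
        cm, truth = synth.generate_expression(cfg, plan)
        # truth covers the whole universe exactly once
        assert len(truth) == 1500
        assert truth.index.equals(cm.feature_ids)
        assert (truth["role"] == "signature_up").sum() == 17
        assert (truth["role"] == "signature_down").sum() == 7

    def test_overlapping_planted_sets_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            synth.SignaturePlan(up_genes={"X": 2.0}, down_genes={"X": -2.0})

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            synth.GeneratorConfig(dispersion=0.0)

    def test_null_gene_sample_means_match_planted_nb_means(self):
        # flat dispersion; compare per-gene sample means to the analytic
        # expectation reconstructed from truth baselines and library sizes
        cfg = synth.GeneratorConfig(
            n_genes=10_000, dispersion=0.1, dispersion_floor=None, seed=5
        )
        cm, truth = synth.generate_expression(cfg, synth.SignaturePlan())
        lam = truth["baseline"].values
        libs = cm.samples.loc[cm.sample_ids, "target_lib_size"].values.astype(float)
        mu = lam[:, None] * (libs / lam.sum())
        var = mu + 0.1 * mu**2
        se = np.sqrt(var.sum(axis=1)) / mu.shape[1]
        obs = cm.counts.values.mean(axis=1)
        within = np.abs(obs - mu.mean(axis=1)) <= 3 * se
        assert within.mean() >= 0.99


class TestRepertoireGenerator:
    def test_zero_rates_reproduce_germline_concatenation(self, germline_db):
        plan = synth.RepertoirePlan(
            germline_db=germline_db,
            mutation_rate={"NBC": 0.0},
            error_rate=0.0,
        )
        reads, truth = synth.generate_repertoire(plan, 30, "NBC", seed=2)
        for rid, seq in reads.items():
            row = truth.loc[rid]
            v = germline_db.v[row["v_call"]].seq
            j = germline_db.j[row["j_call"]].seq
            assert seq.startswith(v) and seq.endswith(j)
            assert len(seq) == len(v) + row["junction_length"] + len(j)
            assert row["n_mutations"] == 0 and row["n_errors"] == 0

    def test_mismatch_fraction_matches_binomial_expectation(self, repertoire_plan):
        m, e = 0.0566, 0.008
        reads, truth = synth.generate_repertoire(repertoire_plan, 3000, "IgA", seed=4)
        total_sub = (truth["n_mutations"] + truth["n_errors"]).sum()
        total_bases = sum(len(s) for s in reads.values())
        rate = total_sub / total_bases
        se = np.sqrt((m + e) * (1 - m - e) / total_bases)
        assert abs(rate - (m + e)) < 3 * se

    def test_truth_separates_mutations_from_errors(self, repertoire_plan):
        reads, truth = synth.generate_repertoire(repertoire_plan, 500, "IgG", seed=6)
        frac_mut = truth["n_mutations"].sum() / (
            truth["n_mutations"].sum() + truth["n_errors"].sum()
        )
        expected = 0.0314 / (0.0314 + 0.008)
        assert abs(frac_mut - expected) < 0.03
        # recorded positions really differ from germline
        rid = truth.index[truth["n_mutations"] > 0][0]
        row = truth.loc[rid]
        v = repertoire_plan.germline_db.v[row["v_call"]].seq
        for pos in map(int, row["mutation_positions"].split(";")):
            if pos < len(v):
                assert reads[rid][pos] != v[pos]

    def test_empty_germline_class_rejected(self, germline_db):
        from mbcomics.repertoire import GermlineDB

        empty = GermlineDB(v=germline_db.v, d={}, j=germline_db.j)
        plan = synth.RepertoirePlan(germline_db=empty)
        with pytest.raises(ValueError, match="germline"):
            synth.generate_repertoire(plan, 10, "NBC", seed=0)


class TestAtacGenerator:
    def test_all_shared_plan_yields_no_unique_peaks(self, small_config):
        plan = synth.AtacPlan(
            shared_fraction=1.0, mbc_only_fraction=0.0, nbc_only_fraction=0.0,
            n_dars=100,
        )
        cm, ivs, truth = synth.generate_atac(small_config, plan)
        assert (truth["category"] == "shared").all()

    def test_venn_fractions_realized_within_one_percent(self):
        cfg = synth.GeneratorConfig(n_peaks=10_000, seed=9)
        cm, ivs, truth = synth.generate_atac(cfg, synth.AtacPlan())
        frac = truth["category"].value_counts(normalize=True)
        assert abs(frac["mbc_only"] - 0.436) < 0.01
        assert abs(frac["nbc_only"] - 0.119) < 0.01
        assert abs(frac["shared"] - 0.445) < 0.01

    def test_invalid_venn_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.AtacPlan(shared_fraction=0.9, mbc_only_fraction=0.9,
                           nbc_only_fraction=0.1)

    def test_concordant_dar_count_follows_plan(self, default_expression):
        cfg, cm, truth = default_expression
        ann = synth.generate_annotation(cfg, gene_ids=list(cm.feature_ids))
        _, ivs, dar_truth = synth.generate_atac(
            cfg, synth.AtacPlan(), truth, ann.genes
        )
        n_up = (truth["role"].isin(["signature_up", "extra_up"])).sum()
        n_dn = (truth["role"].isin(["signature_down", "extra_down"])).sum()
        expected = round(0.354 * n_up) + round(0.354 * n_dn)
        linked = dar_truth[dar_truth["linked_gene"] != ""]
        assert len(linked) == expected
        # linked DARs sit within 10 kb of their gene and share its direction
        for pid, row in linked.head(50).iterrows():
            g = ann.genes[row["linked_gene"]]
            assert row["chrom"] == g.chrom
            assert g.start - 10_000 <= row["start"] < g.end + 10_000
            role = truth.loc[row["linked_gene"], "role"]
            assert ("up" in role) == (row["direction"] == "up")


class TestAnnotationGenerator:
    def test_scrubbed_utrs_carry_no_mir181_cores(self, small_config):
        plan = synth.MirnaTargetPlan(targets={})  # zero planted sites
        ann = synth.generate_annotation(
            small_config, plan,
            gene_ids=[f"G{i}" for i in range(40)],
            lncrna_ids=["L1"], mirna_ids=["MIR181A"],
        )
        core = "GAAUGU"  # reverse complement of the MIR181 seed (nt 2-7)
        for seq in ann.utrs.values():
            assert core not in seq
        assert len(ann.site_truth) == 0

    def test_planted_sites_recovered_by_independent_string_search(self, small_config):
        plan = synth.MirnaTargetPlan(
            targets={f"G{i}": ("MIR181A", "7mer-m8", 1) for i in range(5)}
        )
        ann = synth.generate_annotation(
            small_config, plan,
            gene_ids=[f"G{i}" for i in range(30)],
            lncrna_ids=["L1"], mirna_ids=["MIR181A"],
        )
        assert len(ann.site_truth) == 5
        site = "UGAAUGU"  # rc(nt 2-8) of the MIR181A analogue, mRNA sense
        for row in ann.site_truth.itertuples():
            utr = ann.utrs[row.gene]
            assert utr[row.position : row.position + 7] == site
            # exactly one site in that UTR
            assert utr.count(site[1:]) == 1

    def test_default_plan_marks_the_five_signature_targets(self):
        plan = synth.default_mirna_target_plan()
        for g in ("RASSF6", "TOX", "TRERF1", "TRPV3", "RORA"):
            assert plan.targets[g][0] == "MIR181A"
        assert plan.targets["RORA"][2] == 3  # three sites in the RORA UTR
        assert sum(1 for g in plan.targets) == 50

    def test_cis_pairs_placed_on_partner_chromosome(self, small_config):
        ann = synth.generate_annotation(small_config)
        plan = synth.default_mirna_target_plan()
        for lnc, gene in plan.cis_pairs:
            assert ann.lncrnas[lnc].chrom == ann.genes[gene].chrom
            assert ann.lncrnas[lnc].distance(ann.genes[gene]) <= 1_000_000

    def test_annotation_deterministic(self, small_config):
        a1 = synth.generate_annotation(small_config)
        a2 = synth.generate_annotation(small_config)
        assert a1.utrs == a2.utrs
        assert a1.mirna_seqs == a2.mirna_seqs
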