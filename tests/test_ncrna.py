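"""Tests for seed-site scanning, duplex energies and the regulatory screens."""

import numpy as np
import pandas as pd
import pytest

from mbcomics import ncrna
from mbcomics.io import GenomicInterval
from mbcomics.synth import MIR181A_SEQ

# mRNA-sense building blocks for the MIR181A analogue
CORE6 = "GAAUGU"          # pairs miRNA nt 2-7
M8 = "U"                  # pairs miRNA nt 8 (A)
SITE_7M8 = M8 + CORE6
SITE_8MER = M8 + CORE6 + "A"


def _embed(site, left="CCCCCCCCCC", right="GGGGGGGGGG"):
    return left + site + right


class TestSeedSites:
    @pytest.mark.parametrize(
        "site,expected_type,offset",
        [
            (SITE_8MER, "8mer", 0),
            (SITE_7M8 + "G", "7mer-m8", 0),
            ("C" + CORE6 + "A", "7mer-A1", 1),
            ("C" + CORE6 + "G", "6mer", 1),
        ],
    )
    def test_each_canonical_type_classified(self, site, expected_type, offset):
        utr = _embed(site)
        hits = ncrna.find_seed_sites(utr, MIR181A_SEQ)
        assert len(hits) == 1
        assert hits[0].site_type == expected_type
        assert hits[0].position == 10 + offset

    def test_no_sites_in_scrubbed_sequence(self):
        assert ncrna.find_seed_sites("C" * 100, MIR181A_SEQ) == []

    def test_dna_input_and_ambiguous_bases(self):
        utr_dna = _embed(SITE_8MER).replace("U", "T")
        hits = ncrna.find_seed_sites(utr_dna, MIR181A_SEQ)
        assert hits[0].site_type == "8mer"
        assert ncrna.find_seed_sites(_embed("NNNNNNNN"), MIR181A_SEQ) == []

    def test_contained_type_reported_when_full_type_disallowed(self):
        utr = _embed(SITE_8MER)
        hits = ncrna.find_seed_sites(
            utr, MIR181A_SEQ, allowed_types=("7mer-m8", "7mer-A1", "6mer")
        )
        assert len(hits) == 1
        assert hits[0].site_type == "7mer-m8"
        only6 = ncrna.find_seed_sites(utr, MIR181A_SEQ, allowed_types=("6mer",))
        assert only6[0].site_type == "6mer"

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            ncrna.find_seed_sites("ACGU" * 10, "ACGUACG")

    def test_agrees_with_exhaustive_position_scan(self):
        # independent oracle: classify every position of a long random
        # sequence directly from the definition
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGU"), 100_000))
        mir = MIR181A_SEQ
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        core = "".join(comp[b] for b in reversed(mir[1:7]))
        m8 = comp[mir[7]]
        expected = []
        for i in range(len(seq) - 5):
            if seq[i : i + 6] != core:
                continue
            has_m8 = i >= 1 and seq[i - 1] == m8
            has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
            t = ("8mer" if has_m8 and has_a1 else "7mer-m8" if has_m8
                 else "7mer-A1" if has_a1 else "6mer")
            expected.append((i - 1 if has_m8 else i, t))
        got = [(h.position, h.site_type) for h in ncrna.find_seed_sites(seq, mir)]
        assert got == expected
        assert len(expected) > 5  # the random sequence exercises the scan


class TestDuplexEnergy:
    def test_fully_complementary_gc_duplex_matches_stack_table_sum(self):
        from mbcomics.ncrna import _WC_STACKS, DUPLEX_INITIATION

        mir = "GCGCGCGC"
        window = "GCGCGCGC"  # reverse complement of mir, read 5'->3'
        # hand-summed: pairs along the miRNA are (G,C),(C,G),... so the 7
        # stacks alternate GC/CG and CG/GC
        stacks = sum(
            _WC_STACKS[("GC", "CG")] if i % 2 == 0 else _WC_STACKS[("CG", "GC")]
            for i in range(7)
        )
        expected = stacks + DUPLEX_INITIATION
        got = ncrna.duplex_energy(mir, window)
        assert got == pytest.approx(expected)

    def test_no_complementarity_reports_missing(self):
        assert ncrna.duplex_energy("AAAAAAAAAA", "AAAAAAAAAA") is None

    def test_extending_the_window_never_destabilizes(self):
        # every duplex available in the core window stays available after
        # extension, so the optimum is monotone in window containment
        core = SITE_8MER + "ACAC"
        extended = "GG" + core + "GGCC"
        e_core = ncrna.duplex_energy(MIR181A_SEQ, core)
        e_ext = ncrna.duplex_energy(MIR181A_SEQ, extended)
        assert e_core is not None and e_ext is not None
        assert e_ext <= e_core

    def test_window_length_validated(self):
        with pytest.raises(ValueError):
            ncrna.duplex_energy(MIR181A_SEQ, "ACGU")
        with pytest.raises(ValueError):
            ncrna.duplex_energy(MIR181A_SEQ, "ACGU" * 15)

    def test_reported_energies_are_stabilizing(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            w = "".join(rng.choice(list("ACGU"), 20))
            e = ncrna.duplex_energy(MIR181A_SEQ, w)
            assert e is None or e <= 0


def _expr(rows, cols=12, seed=0):
    """Expression frame with prescribed per-feature rank patterns ('up' and
    'down' are exact rank reversals of each other)."""
    rng = np.random.default_rng(seed)
    base = np.concatenate(
        [np.arange(cols // 2), 50.0 + np.arange(cols - cols // 2)]
    )
    data = {}
    for name, kind in rows:
        if kind == "up":
            v = base.copy()
        elif kind == "down":
            v = 100.0 - base
        else:
            v = rng.permutation(cols).astype(float)
        data[name] = v + rng.normal(0, 1e-6, cols)
    return pd.DataFrame(data).T


class TestTargetRelease:
    def _matches(self, pairs):
        return pd.DataFrame(
            [(g, m, 10, t) for g, m, t in pairs],
            columns=["gene", "mirna", "position", "site_type"],
        )

    def test_hand_built_screen_releases_exactly_one_target(self):
        gene_expr = _expr([("g1", "up"), ("g2", "rand"), ("g3", "up")])
        mirna_expr = _expr([("m1", "down")])
        matches = self._matches(
            [("g1", "m1", "7mer-m8"), ("g2", "m1", "7mer-m8")]
        )
        out = ncrna.target_release_screen(
            ["g1", "g2", "g3"], ["m1"], matches, gene_expr, mirna_expr
        )
        # g1: site + strong inverse correlation; g2: site but no correlation;
        # g3: correlated but siteless
        assert out["released_genes"] == ["g1"]
        assert out["targets_by_mirna"] == {"m1": ["g1"]}
        assert out["fraction_up_targeted"] == pytest.approx(1 / 3)

    def test_empty_mirna_set_yields_nothing(self):
        gene_expr = _expr([("g1", "up")])
        out = ncrna.target_release_screen(
            ["g1"], [], self._matches([]), gene_expr, _expr([]),
        )
        assert out["released_genes"] == []
        assert out["fraction_up_targeted"] == 0.0

    def test_min_site_type_excludes_weaker_sites(self):
        gene_expr = _expr([("g1", "up")])
        mirna_expr = _expr([("m1", "down")])
        matches = self._matches([("g1", "m1", "6mer")])
        out = ncrna.target_release_screen(
            ["g1"], ["m1"], matches, gene_expr, mirna_expr,
            min_site_type="7mer-m8",
        )
        assert out["released_genes"] == []
        out2 = ncrna.target_release_screen(
            ["g1"], ["m1"], matches, gene_expr, mirna_expr, min_site_type="6mer"
        )
        assert out2["released_genes"] == ["g1"]

    def test_missing_expression_excluded_and_counted(self):
        gene_expr = _expr([("g1", "up")])
        mirna_expr = _expr([("m1", "down")])
        matches = self._matches(
            [("g1", "m1", "8mer"), ("ghost", "m1", "8mer")]
        )
        out = ncrna.target_release_screen(
            ["g1", "ghost"], ["m1"], matches, gene_expr, mirna_expr
        )
        assert out["n_skipped_missing_expression"] == 1


class TestCoexpression:
    def _ivs(self):
        return (
            {"L1": GenomicInterval("chr1", 1000, 2000, "L1"),
             "L2": GenomicInterval("chr2", 1000, 2000, "L2")},
            {"g1": GenomicInterval("chr1", 500_000, 501_000, "g1"),
             "g2": GenomicInterval("chr3", 1000, 2000, "g2")},
        )

    def test_relation_labels(self):
        lnc_iv, g_iv = self._ivs()
        lnc = _expr([("L1", "up"), ("L2", "up")], seed=1)
        genes = _expr([("g1", "up"), ("g2", "down")], seed=2)
        out = ncrna.lncrna_coexpression(lnc, genes, lnc_iv, g_iv)
        rec = out["records"].set_index(["lncrna", "partner"])
        assert rec.loc[("L1", "g1"), "relation"] == "cis"     # 498 kb gap
        assert rec.loc[("L1", "g2"), "relation"] == "trans"   # other chrom
        assert rec.loc[("L2", "g1"), "relation"] == "trans"

    def test_identical_vectors_correlate_perfectly(self):
        lnc_iv, g_iv = self._ivs()
        v = _expr([("L1", "up")], seed=3)
        g = v.rename(index={"L1": "g1"})
        out = ncrna.lncrna_coexpression(v, g, lnc_iv, g_iv, pairs=[("L1", "g1")])
        assert out["records"]["r_s"].iloc[0] == pytest.approx(1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        lnc_iv, g_iv = self._ivs()
        lnc = _expr([("L1", "rand")], seed=4)
        g = pd.DataFrame([np.exp(lnc.loc["L1"].values / 10)], index=["g1"])
        out = ncrna.lncrna_coexpression(lnc, g, lnc_iv, g_iv, pairs=[("L1", "g1")])
        assert out["records"]["r_s"].iloc[0] == pytest.approx(1.0)

    def test_constant_vectors_excluded(self):
        lnc_iv, g_iv = self._ivs()
        lnc = pd.DataFrame([np.full(12, 5.0)], index=["L1"])
        g = _expr([("g1", "up")], seed=5)
        out = ncrna.lncrna_coexpression(lnc, g, lnc_iv, g_iv, pairs=[("L1", "g1")])
        assert out["n_excluded_constant"] == 1
        assert len(out["records"]) == 0

    def test_latent_factor_pairs_detected_at_planted_fraction(self):
        # 300 cis-like pairs, 15 driven by a shared latent factor
        from mbcomics import synth
        from mbcomics.diffexpr import CountMatrix

        rng = np.random.default_rng(9)
        n = 300
        lnc_counts = pd.DataFrame(
            rng.poisson(100, size=(n, 12)),
            index=[f"L{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(12)],
        )
        g_counts = pd.DataFrame(
            rng.poisson(100, size=(n, 12)),
            index=[f"g{i}" for i in range(n)], columns=lnc_counts.columns,
        )
        samples = pd.DataFrame({"subset": ["A"] * 12}, index=lnc_counts.columns)
        cm_l = CountMatrix(lnc_counts, samples)
        cm_g = CountMatrix(g_counts, samples)
        driven = [(f"L{i}", f"g{i}", 0.9) for i in range(15)]
        cm_l, cm_g = synth.apply_coexpression(cm_l, cm_g, driven, seed=1)
        ivs_l = {f"L{i}": GenomicInterval("chr1", 1000 * i + 1, 1000 * i + 500)
                 for i in range(n)}
        ivs_g = {f"g{i}": GenomicInterval("chr1", 1000 * i + 600, 1000 * i + 900)
                 for i in range(n)}
        out = ncrna.lncrna_coexpression(
            cm_l.counts.astype(float), cm_g.counts.astype(float),
            ivs_l, ivs_g, pairs=[(f"L{i}", f"g{i}") for i in range(n)],
        )
        frac = out["summary"]["cis"]["fraction_positive"]
        assert abs(frac - 15 / 300) < 0.02


class TestSpongeScreen:
    def test_hand_built_sponge_detected(self):
        lnc = _expr([("MIAT", "up")], seed=10)
        mir = _expr([("m1", "down")], seed=11)
        genes = _expr([("t1", "up"), ("t2", "up")], seed=12)
        release = {"targets_by_mirna": {"m1": ["t1", "t2"]}}
        out = ncrna.sponge_screen(["MIAT"], ["m1"], release, lnc, mir, genes)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["lncrna"] == "MIAT" and not row["partial"]
        assert row["median_r_s_targets"] > 0

    def test_no_upregulated_lncrnas_gives_empty(self):
        out = ncrna.sponge_screen(
            [], ["m1"], {"targets_by_mirna": {}}, _expr([]), _expr([("m1", "down")]),
            _expr([]),
        )
        assert out.empty

    def test_mirna_without_targets_flagged_partial(self):
        lnc = _expr([("MIAT", "up")], seed=13)
        mir = _expr([("m1", "down")], seed=14)
        out = ncrna.sponge_screen(
            ["MIAT"], ["m1"], {"targets_by_mirna": {}}, lnc, mir, _expr([])
        )
        assert len(out) == 1 and bool(out.iloc[0]["partial"])

    def test_positively_correlated_mirna_is_not_a_sponge_partner(self):
        lnc = _expr([("MIAT", "up")], seed=15)
        mir = _expr([("m1", "up")], seed=16)  # same direction as the lncRNA
        out = ncrna.sponge_screen(
            ["MIAT"], ["m1"], {"targets_by_mirna": {}}, lnc, mir, _expr([])
        )
        assert out.empty
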