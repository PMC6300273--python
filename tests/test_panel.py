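"""Panel loading, validation, risk orientation and variant filters."""

import numpy as np
import pandas as pd
import pytest

from bpgrs.errors import HarmonizationError, PanelValidationError
from bpgrs.panel import (
    Panel,
    apply_mac_filter,
    ld_prune,
    load_panel,
    minor_allele_count,
    orient_to_risk,
    resolve_proxies,
    subset_by_trait,
)

from conftest import make_gm, make_panel, make_variant

HEADER = ("rsid\tchrom\tpos\teffect_allele\tother_allele\t"
          "beta_sbp\tbeta_dbp\tbeta_pp\ttraits\n")


def write_panel_tsv(path, rows):
    path.write_text(HEADER + "".join(rows))
    return path


class TestLoadPanel:
    def test_well_formed_three_rows(self, tmp_path):
        p = write_panel_tsv(tmp_path / "p.tsv", [
            "rs1\t1\t100\tA\tG\t0.5\t\t\tSBP\n",
            "rs2\t2\t200\tC\tT\t\t-0.3\t\tDBP\n",
            "rs3\t3\t300\tG\tA\t0.4\t\t0.2\tSBP,PP\n",
        ])
        panel = load_panel(p)
        assert panel.N == 3
        assert panel.exclusions == []
        assert panel.get("rs3").traits == {"SBP", "PP"}
        assert panel.get("rs3").beta == 0.4  # combined = largest |beta|
        assert panel.get("rs2").beta == -0.3

    def test_duplicate_rsid_rejected(self, tmp_path):
        p = write_panel_tsv(tmp_path / "p.tsv", [
            "rs1\t1\t100\tA\tG\t0.5\t\t\tSBP\n",
            "rs1\t1\t100\tA\tG\t0.5\t\t\tSBP\n",
        ])
        with pytest.raises(PanelValidationError, match="rs1"):
            load_panel(p)

    def test_unknown_trait_rejected(self, tmp_path):
        p = write_panel_tsv(tmp_path / "p.tsv", ["rs1\t1\t100\tA\tG\t0.5\t\t\tMAP\n"])
        with pytest.raises(PanelValidationError, match="MAP"):
            load_panel(p)

    def test_missing_beta_for_claimed_trait(self, tmp_path):
        p = write_panel_tsv(tmp_path / "p.tsv", ["rs1\t1\t100\tA\tG\t\t\t\tSBP\n"])
        with pytest.raises(PanelValidationError, match="row 0"):
            load_panel(p)

    def test_missing_allele_row_indexed(self, tmp_path):
        p = write_panel_tsv(tmp_path / "p.tsv", [
            "rs1\t1\t100\tA\tG\t0.5\t\t\tSBP\n",
            "rs2\t1\t200\t\tG\t0.5\t\t\tSBP\n",
        ])
        with pytest.raises(PanelValidationError, match="row 1"):
            load_panel(p)

    def test_large_fixture_row_count(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [
            f"rs{j}\t{j % 22 + 1}\t{j * 10}\tA\tC\t{rng.exponential(0.5):.4f}\t\t\tSBP\n"
            for j in range(1, 267)
        ]
        path = write_panel_tsv(tmp_path / "big.tsv", rows)
        # independent oracle: number of data lines in the file
        n_lines = sum(1 for _ in open(path)) - 1
        panel = load_panel(path)
        assert panel.N == n_lines == 266


class TestOrientToRisk:
    def test_negative_beta_flips_alleles_and_dosage(self):
        panel = Panel([make_variant("rs1", -0.5, effect="A", other="G")])
        gm = make_gm([[0.5]], panel)
        out_panel, out_gm = orient_to_risk(panel, gm)
        v = out_panel.get("rs1")
        assert (v.effect_allele, v.other_allele) == ("G", "A")
        assert v.beta == 0.5
        assert out_gm.column("rs1")[0] == pytest.approx(1.5)

    def test_positive_panel_is_identity(self):
        panel = make_panel([0.3, 0.7])
        gm = make_gm([[0, 1], [2, 1]], panel)
        out_panel, out_gm = orient_to_risk(panel, gm)
        assert out_panel.variants == panel.variants
        np.testing.assert_array_equal(out_gm.dosage, gm.dosage)

    def test_allele_swap_harmonized(self):
        # genotype file counts the panel's other allele: dosage flips once
        panel = Panel([make_variant("rs1", 0.4, effect="A", other="G")])
        gm = make_gm([[2.0]], panel, allele_ref={"rs1": ("G", "A")})
        out_panel, out_gm = orient_to_risk(panel, gm)
        assert out_gm.column("rs1")[0] == pytest.approx(0.0)
        assert out_gm.allele_ref["rs1"] == ("A", "G")

    def test_mismatched_alleles_raise(self):
        panel = Panel([make_variant("rs1", 0.4, effect="A", other="G")])
        gm = make_gm([[1.0]], panel, allele_ref={"rs1": ("C", "T")})
        with pytest.raises(HarmonizationError, match="rs1"):
            orient_to_risk(panel, gm)

    def test_zero_beta_raises(self):
        panel = Panel([make_variant("rs1", 0.0)])
        gm = make_gm([[1.0]], panel)
        with pytest.raises(HarmonizationError, match="no risk direction"):
            orient_to_risk(panel, gm)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        betas = rng.normal(0, 0.5, 20)
        betas[betas == 0] = 0.1
        panel = make_panel(betas)
        gm = make_gm(rng.integers(0, 3, (30, 20)), panel)
        p1, g1 = orient_to_risk(panel, gm)
        p2, g2 = orient_to_risk(p1, g1)
        assert p1.variants == p2.variants
        np.testing.assert_array_equal(g1.dosage, g2.dosage)

    def test_score_invariance_against_loop_oracle(self):
        # uGRS on the oriented data equals a per-element loop over flipped
        # dosages computed independently of the orientation code
        rng = np.random.default_rng(6)
        betas = rng.normal(0, 0.5, 20)
        betas[np.abs(betas) < 1e-3] = 0.2
        panel = make_panel(betas)
        dos = rng.integers(0, 3, (25, 20)).astype(float)
        gm = make_gm(dos, panel)
        p1, g1 = orient_to_risk(panel, gm)
        got = g1.dosage.sum(axis=1)
        expected = np.zeros(25)
        for i in range(25):
            for j in range(20):
                s = dos[i, j]
                expected[i] += (2 - s) if betas[j] < 0 else s
        np.testing.assert_allclose(got, expected)

    def test_drop_ambiguous_flag(self):
        panel = Panel([
            make_variant("rs1", 0.3, effect="A", other="T"),
            make_variant("rs2", 0.3, effect="A", other="C"),
        ])
        gm = make_gm([[1, 1], [0, 2]], panel)
        with pytest.warns(UserWarning, match="strand-ambiguous"):
            kept, _ = orient_to_risk(panel, gm)
        assert kept.N == 2
        dropped, _ = orient_to_risk(panel, gm, drop_ambiguous=True)
        assert dropped.rsids == ["rs2"]
        assert dropped.exclusions[0].rule == "strand_ambiguous"


class TestMacFilter:
    def test_strict_threshold_boundary(self):
        # MAC 19 removed, MAC 20 and 25 kept at threshold 20
        n = 100
        cols = []
        for mac in (19, 20, 25):
            col = np.zeros(n)
            col[:mac] = 1.0
            cols.append(col)
        panel = make_panel([0.1, 0.2, 0.3])
        gm = make_gm(np.column_stack(cols), panel)
        out = apply_mac_filter(panel, gm, threshold=20)
        assert out.rsids == ["rs2", "rs3"]
        assert [e.rsid for e in out.exclusions] == ["rs1"]
        assert out.exclusions[0].rule == "mac_lt_20"

    def test_monomorphic_excluded(self):
        panel = make_panel([0.1])
        gm = make_gm(np.zeros((50, 1)), panel)
        out = apply_mac_filter(panel, gm)
        assert out.N == 0

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, (60, 50)).astype(float)
        dos[rng.random((60, 50)) < 0.05] = np.nan
        panel = make_panel(rng.exponential(0.5, 50) + 0.01)
        gm = make_gm(dos, panel)
        out = apply_mac_filter(panel, gm, threshold=40)
        expected = []
        for j, v in enumerate(panel):
            alt = het = other = 0
            for i in range(60):
                s = dos[i, j]
                if not np.isnan(s):
                    alt += s
                    other += 2 - s
            if min(alt, other) >= 40:
                expected.append(v.rsid)
        assert out.rsids == expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        panel = make_panel(np.full(30, 0.2))
        gm = make_gm(rng.integers(0, 3, (80, 30)), panel)
        sizes = [apply_mac_filter(panel, gm, threshold=t).N for t in range(0, 90, 10)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestResolveProxies:
    proxy_map = pd.DataFrame({
        "index_rsid": ["rs10", "rs20", "rs30"],
        "proxy_rsid": ["rs11", "rs21", "rs31"],
        "r2": [0.95, 0.79, 0.9],
    })

    def test_substitution_records_provenance(self):
        panel = Panel([make_variant("rs10", 0.5), make_variant("rs1", 0.3)])
        out = resolve_proxies(panel, self.proxy_map, {"rs11", "rs1"})
        assert out.rsids == ["rs11", "rs1"]
        v = out.get("rs11")
        assert v.proxy_of == "rs10" and v.proxy_r2 == 0.95
        assert v.beta == 0.5  # index SNP's weight is carried over

    def test_below_threshold_proxy_dropped_no_proxy(self):
        panel = Panel([make_variant("rs20", 0.5)])
        out = resolve_proxies(panel, self.proxy_map, {"rs21"})
        assert out.N == 0
        assert out.exclusions[0].rule == "no_proxy"  # 0.79 < 0.8

    def test_proxy_not_genotyped_distinct_code(self):
        panel = Panel([make_variant("rs30", 0.5)])
        out = resolve_proxies(panel, self.proxy_map, {"rs99"})
        assert out.N == 0
        assert out.exclusions[0].rule == "proxy_not_genotyped"

    def test_all_present_is_identity(self):
        panel = make_panel([0.1, 0.2, 0.3])
        out = resolve_proxies(panel, self.proxy_map, set(panel.rsids))
        assert out.variants == panel.variants
        assert out.exclusions == []

    def test_invalid_r2_rejected(self):
        bad = pd.DataFrame({"index_rsid": ["a"], "proxy_rsid": ["b"], "r2": [1.2]})
        with pytest.raises(PanelValidationError):
            resolve_proxies(make_panel([0.1]), bad, set())


class TestLdPrune:
    def test_perfect_correlation_keeps_larger_beta(self):
        rng = np.random.default_rng(9)
        col = rng.integers(0, 3, 40).astype(float)
        panel = make_panel([0.3, 0.5])
        gm = make_gm(np.column_stack([col, col]), panel)
        out = ld_prune(panel, gm)
        assert out.rsids == ["rs2"]  # beta 0.5 wins
        assert out.exclusions[0].rsid == "rs1"

    def test_tie_removes_later_panel_order(self):
        rng = np.random.default_rng(10)
        col = rng.integers(0, 3, 40).astype(float)
        panel = make_panel([0.3, 0.3])
        gm = make_gm(np.column_stack([col, col]), panel)
        out = ld_prune(panel, gm)
        assert out.rsids == ["rs1"]

    def test_independent_variants_untouched(self):
        rng = np.random.default_rng(12)
        panel = make_panel(rng.exponential(0.5, 20) + 0.01)
        gm = make_gm(rng.integers(0, 3, (500, 20)), panel)
        out = ld_prune(panel, gm, r2_threshold=0.8)
        assert out.rsids == panel.rsids

    def test_single_variant_unchanged(self):
        panel = make_panel([0.4])
        gm = make_gm([[1.0], [2.0]], panel)
        assert ld_prune(panel, gm).rsids == ["rs1"]

    def test_zero_variance_warned_never_removed(self):
        rng = np.random.default_rng(13)
        panel = make_panel([0.1, 0.2])
        gm = make_gm(
            np.column_stack([np.ones(40), rng.integers(0, 3, 40)]), panel
        )
        with pytest.warns(UserWarning, match="zero dosage variance"):
            out = ld_prune(panel, gm)
        assert "rs1" in out.rsids


class TestSubsetByTrait:
    def multi_panel(self):
        v1 = make_variant("rs1", 0.5, traits=["SBP", "PP"])
        v2 = make_variant("rs2", 0.3, traits=["DBP"])
        v3 = make_variant("rs3", 0.2, traits=["SBP"])
        return Panel([v1, v2, v3])

    def test_multi_trait_variant_in_each_trait_panel(self):
        panel = self.multi_panel()
        assert "rs1" in subset_by_trait(panel, "SBP").rsids
        assert "rs1" in subset_by_trait(panel, "PP").rsids
        assert "rs1" not in subset_by_trait(panel, "DBP").rsids

    def test_trait_beta_carried(self):
        panel = Panel([VS_with_two_betas()])
        sub = subset_by_trait(panel, "PP")
        assert sub.get("rsx").beta == 0.2

    def test_empty_trait_panel_errors(self):
        panel = Panel([make_variant("rs1", 0.5, traits=["SBP"])])
        with pytest.raises(PanelValidationError, match="DBP"):
            subset_by_trait(panel, "DBP")

    def test_union_of_trait_panels_covers_full_panel(self):
        panel = self.multi_panel()
        union = set()
        for t in ("SBP", "DBP", "PP"):
            union |= set(subset_by_trait(panel, t).rsids)
        assert union == set(panel.rsids)


def VS_with_two_betas():
    from bpgrs.panel import VariantSpec

    return VariantSpec(
        rsid="rsx", chrom="1", pos=1, effect_allele="A", other_allele="G",
        betas={"SBP": 0.5, "PP": 0.2}, beta=0.5,
    )


def test_every_exclusion_logged_exactly_once():
    rng = np.random.default_rng(14)
    panel = make_panel(np.full(20, 0.2))
    dos = rng.integers(0, 3, (100, 20)).astype(float)
    dos[:, 0] = 0.0  # monomorphic -> MAC exclusion
    gm = make_gm(dos, panel)
    out = apply_mac_filter(panel, gm, threshold=20)
    removed = set(panel.rsids) - set(out.rsids)
    logged = [e.rsid for e in out.exclusions]
    assert sorted(logged) == sorted(removed)
    assert len(logged) == len(set(logged))


def test_minor_allele_count_ignores_missing():
    col = np.array([0, 1, 2, np.nan, 2])
    assert minor_allele_count(col) == pytest.approx(3.0)  # min(5, 8-5)
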