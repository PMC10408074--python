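import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regdriver.germline import (
    PWM,
    SNPRecord,
    StandardCurve,
    allelic_imbalance,
    cooccupancy_categories,
    expand_proxies,
    fit_standard_curve,
    ld_r2,
    map_eqtl_genes,
    pwm_allele_delta,
    qpcr_quantify,
    read_pwm,
    read_snp_table,
    read_vcf_snps,
    snp_peak_enrichment,
    write_pwm,
)
from regdriver.intervals import GenomicInterval, PeakSet
from regdriver.simulate import SimConfig, gen_germline, gen_peaksets


class TestSNPRecord:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SNPRecord("rs1", "chr1", 10, "A", "A")
        with pytest.raises(ValueError):
            SNPRecord("rs1", "chr1", 10, "A", "N")
        with pytest.raises(ValueError):
            SNPRecord("rs1", "chr1", 10, "A", "C", risk_allele="G")

    def test_other_allele(self):
        snp = SNPRecord("rs1", "chr1", 10, "C", "T", risk_allele="T")
        assert snp.other_allele == "C"


class TestLdR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0])
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        g = np.array([0, 1, 2, 1, 0])
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_monomorphic_flagged(self):
        assert math.isnan(ld_r2(np.ones(5), np.array([0, 1, 2, 1, 0])))

    def test_matches_squared_pearson_oracle(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, size=50).astype(float)
            b = rng.integers(0, 3, size=50).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            r, _ = stats.pearsonr(a, b)
            assert ld_r2(a, b) == pytest.approx(r * r, abs=1e-12)

    def test_pairwise_complete(self):
        a = np.array([0, 1, 2, np.nan, 1])
        b = np.array([0, 1, 2, 0, np.nan])
        assert ld_r2(a, b) == pytest.approx(1.0)


def snp_df(rows):
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos"])


class TestExpandProxies:
    def test_inclusive_r2_cutoff(self):
        # construct two dosage vectors with r2 exactly 0.5
        g_tag = np.array([0.0, 0, 1, 1, 2, 2, 0, 2])
        g_prox = np.array([0.0, 1, 0, 2, 1, 2, 1, 2])
        r2 = ld_r2(g_tag, g_prox)
        geno = pd.DataFrame([g_tag, g_prox], index=["tag", "prox"])
        snps = snp_df([("tag", "chr1", 100), ("prox", "chr1", 200)])
        out = expand_proxies(["tag"], snps, genotypes=geno, r2_min=r2)
        assert set(out["proxy"]) == {"tag", "prox"}
        out2 = expand_proxies(["tag"], snps, genotypes=geno, r2_min=r2 + 1e-9)
        assert set(out2["proxy"]) == {"tag"}

    def test_lone_tag_is_own_proxy(self):
        geno = pd.DataFrame([[0, 1, 2, 1]], index=["tag"])
        out = expand_proxies(["tag"], snp_df([("tag", "chr1", 100)]), genotypes=geno)
        assert list(out["proxy"]) == ["tag"]
        assert out.loc[0, "r2"] == 1.0

    def test_window_limits(self):
        g = np.array([0.0, 1, 2, 1, 0, 2])
        geno = pd.DataFrame([g, g, g], index=["tag", "near", "far"])
        snps = snp_df(
            [("tag", "chr1", 0), ("near", "chr1", 500), ("far", "chr1", 2_000_001)]
        )
        out = expand_proxies(["tag"], snps, genotypes=geno, window_bp=1_000_000)
        assert set(out["proxy"]) == {"tag", "near"}

    def test_missing_tag_reported(self):
        out = expand_proxies(["ghost"], snp_df([("x", "chr1", 1)]),
                             genotypes=pd.DataFrame([[0, 1, 2]], index=["x"]))
        assert not out.loc[0, "tag_found"]

    def test_precomputed_ld_table(self):
        snps = snp_df([("tag", "chr1", 100), ("p1", "chr1", 200)])
        ld = pd.DataFrame({"tag": ["tag"], "proxy": ["p1"], "r2": [0.7]})
        out = expand_proxies(["tag"], snps, ld_pairs=ld)
        assert set(out["proxy"]) == {"tag", "p1"}

    def test_r2_bounds_properties(self):
        # r2_min=0 returns every (polymorphic) SNP in the window;
        # r2_min=1 returns the tag plus perfect proxies only
        r = np.random.default_rng(2)
        g_tag = r.integers(0, 3, size=60).astype(float)
        geno = pd.DataFrame(
            [g_tag, g_tag.copy(), r.integers(0, 3, size=60).astype(float)],
            index=["tag", "perfect", "random"],
        )
        snps = snp_df([("tag", "chr1", 0), ("perfect", "chr1", 10), ("random", "chr1", 20)])
        all_out = expand_proxies(["tag"], snps, genotypes=geno, r2_min=0.0)
        assert set(all_out["proxy"]) == {"tag", "perfect", "random"}
        strict = expand_proxies(["tag"], snps, genotypes=geno, r2_min=1.0)
        assert set(strict["proxy"]) == {"tag", "perfect"}

    def test_planted_ld_block_recovered(self):
        cfg = SimConfig(seed=9, n_peaks_a=200, n_peaks_b=200, ld_target_r2=0.8,
                        n_background_snps=200, n_risk_snps=20)
        peaks = gen_peaksets(cfg)
        germ = gen_germline(cfg, peaks.peaks_a, peaks.peaks_b)
        tag = "rs_tag0"
        members = set(germ.truth["ld_blocks"][tag])
        out = expand_proxies([tag], germ.snps, genotypes=germ.genotypes, r2_min=0.5)
        assert members <= set(out["proxy"])


class TestSnpPeakEnrichment:
    @staticmethod
    def toy_sets():
        a = PeakSet("A", [GenomicInterval("chr1", 0, 1000),
                          GenomicInterval("chr1", 5000, 6000)])
        b = PeakSet("B", [GenomicInterval("chr1", 500, 1500),
                          GenomicInterval("chr1", 8000, 9000)])
        return a, b

    def test_categories_partition(self):
        a, b = self.toy_sets()
        cats = cooccupancy_categories(a, b)
        assert cats["common"].total_bases() == 500
        assert cats["a_only"].total_bases() == 1500
        assert cats["b_only"].total_bases() == 1500

    def test_fold_arithmetic_and_bounds(self, rng):
        a, b = self.toy_sets()
        snps = pd.DataFrame({"chrom": ["chr1"] * 5,
                             "pos": [600, 700, 800, 3000, 4000]})
        bg = pd.DataFrame({"chrom": ["chr1"] * 200,
                           "pos": rng.integers(0, 10_000, size=200)})
        out = snp_peak_enrichment(snps, a, b, bg, n_perm=100, seed=0)
        assert set(out["category"]) == {"a_only", "b_only", "common"}
        assert ((out["p_value"] >= 1 / 101) & (out["p_value"] <= 1.0)).all()
        common = out.set_index("category").loc["common"]
        assert common["observed"] == 3
        assert common["fold"] == pytest.approx(3 / common["null_mean"])

    def test_background_smaller_than_snps_errors(self):
        a, b = self.toy_sets()
        snps = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1, 2, 3]})
        bg = pd.DataFrame({"chrom": ["chr1"], "pos": [1]})
        with pytest.raises(ValueError):
            snp_peak_enrichment(snps, a, b, bg)

    def test_reproducible_given_seed(self, rng):
        a, b = self.toy_sets()
        snps = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": [600, 700, 800, 3000, 4000]})
        bg = pd.DataFrame({"chrom": ["chr1"] * 100,
                           "pos": rng.integers(0, 10_000, size=100)})
        o1 = snp_peak_enrichment(snps, a, b, bg, n_perm=200, seed=42)
        o2 = snp_peak_enrichment(snps, a, b, bg, n_perm=200, seed=42)
        pd.testing.assert_frame_equal(o1, o2)

    def test_self_background_fold_near_1(self):
        r = np.random.default_rng(13)
        a, b = self.toy_sets()
        bg = pd.DataFrame({"chrom": ["chr1"] * 500,
                           "pos": r.integers(0, 10_000, size=500)})
        snps = bg.sample(50, random_state=1)
        out = snp_peak_enrichment(snps, a, b, bg, n_perm=500, seed=7)
        common = out.set_index("category").loc["common"]
        if common["observed"] > 0:
            assert 0.5 < common["fold"] < 2.0


class TestMapEqtlGenes:
    def test_link_to_egene(self):
        proxies = pd.DataFrame({"tag": ["rs_tag"], "proxy": ["rs_example"]})
        eqtl = pd.DataFrame({"rsid": ["rs_example"], "egene": ["EG_EX"]})
        out = map_eqtl_genes(proxies, eqtl)
        assert out.loc[0, "egene"] == "EG_EX"

    def test_empty_eqtl_table_keeps_loci(self):
        proxies = pd.DataFrame({"tag": ["t"], "proxy": ["p"]})
        out = map_eqtl_genes(proxies, pd.DataFrame(columns=["rsid", "egene"]))
        assert len(out) == 1 and out.loc[0, "egene"] == ""

    def test_row_count_matches_join_oracle(self, rng):
        proxies = pd.DataFrame(
            {"tag": [f"t{i % 3}" for i in range(20)],
             "proxy": [f"p{rng.integers(0, 10)}" for _ in range(20)]}
        )
        eqtl = pd.DataFrame(
            {"rsid": [f"p{rng.integers(0, 10)}" for _ in range(15)],
             "egene": [f"E{i}" for i in range(15)]}
        )
        out = map_eqtl_genes(proxies, eqtl)
        expected = 0
        for p in proxies["proxy"]:
            hits = (eqtl["rsid"] == p).sum()
            expected += max(hits, 1)
        assert len(out) == expected


class TestPwmAlleleDelta:
    @staticmethod
    def single_pos_pwm():
        return PWM("t_vs_c", np.array([[0.10, 0.05, 0.05, 0.80]]), pseudocount=0.0)

    def test_uniform_pwm_delta_zero(self):
        pwm = PWM("uni", np.full((3, 4), 0.25), pseudocount=0.0)
        snp = SNPRecord("rs1", "chr1", 5, "C", "T", risk_allele="T")
        seq = "AACCACGGTT"
        best_ref, best_alt, delta, pref = pwm_allele_delta(pwm, seq, snp, 5)
        assert best_ref == pytest.approx(0.0)
        assert best_alt == pytest.approx(0.0)
        assert delta == pytest.approx(0.0)
        assert pref == "none"

    def test_hand_log_odds_arithmetic(self):
        # single position, p(T)=0.8 vs p(C)=0.05, uniform background:
        # delta = log2(0.8/0.25) - log2(0.05/0.25) = 4 bits
        snp = SNPRecord("rs1", "chr1", 1, "C", "T", risk_allele="T")
        _, _, delta, pref = pwm_allele_delta(self.single_pos_pwm(), "ACA", snp, 1)
        assert delta == pytest.approx(4.0, abs=1e-9)
        assert pref == "T"

    def test_antisymmetric_under_allele_swap(self, rng):
        pwm = PWM("m", rng.dirichlet(np.ones(4), size=6))
        left = "".join(rng.choice(list("ACGT"), size=8))
        right = "".join(rng.choice(list("ACGT"), size=8))
        seq_ref = left + "A" + right
        seq_alt = left + "G" + right
        snp = SNPRecord("rs1", "chr1", 8, "A", "G")
        swapped = SNPRecord("rs1", "chr1", 8, "G", "A")
        _, _, d1, _ = pwm_allele_delta(pwm, seq_ref, snp, 8)
        _, _, d2, _ = pwm_allele_delta(pwm, seq_alt, swapped, 8)
        assert d1 == pytest.approx(-d2, abs=1e-12)

    def test_sequence_ref_mismatch_errors(self):
        snp = SNPRecord("rs1", "chr1", 1, "C", "T")
        with pytest.raises(ValueError, match="expected ref"):
            pwm_allele_delta(self.single_pos_pwm(), "AAA", snp, 1)

    def test_non_acgt_errors(self):
        snp = SNPRecord("rs1", "chr1", 1, "C", "T")
        with pytest.raises(ValueError, match="non-ACGT"):
            pwm_allele_delta(self.single_pos_pwm(), "ACN", snp, 1)

    def test_planted_consensus_prefers_risk_allele(self):
        cfg = SimConfig(seed=21, n_peaks_a=200, n_peaks_b=200,
                        n_background_snps=100, n_risk_snps=10)
        peaks = gen_peaksets(cfg)
        germ = gen_germline(cfg, peaks.peaks_a, peaks.peaks_b)
        info = germ.truth["motif_snp"]
        snp = SNPRecord("rs_motif", "chr1", 0, "C", "T", risk_allele="T")
        _, _, delta, pref = pwm_allele_delta(
            germ.pwm, germ.sequences["rs_motif"], snp, info["snp_offset"]
        )
        assert pref == info["risk_allele"]
        assert delta > 0


def binomial_two_sided_oracle(k, n):
    """Exhaustive enumeration: sum of point probabilities <= P(observed)."""
    probs = np.array([math.comb(n, i) * 0.5**n for i in range(n + 1)])
    return float(probs[probs <= probs[k] * (1 + 1e-12)].sum())


class TestAllelicImbalance:
    def test_balanced_counts(self):
        ratio, p = allelic_imbalance(5, 5)
        assert ratio == 0.5 and p == 1.0

    def test_9_vs_1(self):
        # exact enumeration: 2 * (C(10,0)+C(10,1)) / 1024 = 22/1024
        ratio, p = allelic_imbalance(9, 1)
        assert ratio == pytest.approx(0.9)
        assert p == pytest.approx(22 / 1024)

    def test_total_zero_errors(self):
        with pytest.raises(ValueError):
            allelic_imbalance(0, 0)

    def test_matches_enumeration_small_totals(self):
        for n in range(1, 16):
            for k in range(n + 1):
                _, p = allelic_imbalance(k, n - k)
                assert p == pytest.approx(binomial_two_sided_oracle(k, n), rel=1e-9)

    def test_null_uniformity(self):
        r = np.random.default_rng(3)
        pvals = [allelic_imbalance(int(k), 100 - int(k))[1]
                 for k in r.binomial(100, 0.5, size=1000)]
        ks = stats.kstest(np.array(pvals), "uniform", alternative="greater")
        assert ks.pvalue > 0.01


class TestQpcr:
    def test_ct_equals_intercept_gives_quantity_1(self):
        curve = StandardCurve(slope=-3.32, intercept=20.0, r2=1.0)
        assert qpcr_quantify(curve, 20.0) == pytest.approx(1.0)

    def test_control_normalization_identity(self):
        curve = StandardCurve(slope=-3.32, intercept=20.0, r2=1.0)
        assert qpcr_quantify(curve, 24.5, control_ct=24.5) == pytest.approx(1.0)

    def test_dilution_series_regenerated(self):
        q = 10.0 ** -np.arange(6)
        slope, intercept = -3.4, 21.7
        ct = slope * np.log10(q) + intercept
        curve = fit_standard_curve(ct, np.log10(q))
        assert curve.r2 == pytest.approx(1.0)
        back = qpcr_quantify(curve, ct)
        assert np.allclose(back, q, rtol=1e-9)

    def test_zero_slope_errors(self):
        with pytest.raises(ValueError):
            qpcr_quantify(StandardCurve(0.0, 20.0, 1.0), 20.0)

    def test_non_finite_ct_errors(self):
        with pytest.raises(ValueError):
            qpcr_quantify(StandardCurve(-3.3, 20.0, 1.0), math.nan)

    def test_allelic_ratio_from_ct_pair(self):
        # per-allele quantities give the allelic ratio via the same formula
        curve = StandardCurve(slope=-3.32, intercept=20.0, r2=1.0)
        ratio = qpcr_quantify(curve, 20.0, control_ct=20.0 - 3.32)
        assert ratio == pytest.approx(0.1)


class TestIO:
    def test_pwm_round_trip(self, rng, tmp_path):
        pwm = PWM("m", rng.dirichlet(np.ones(4), size=5))
        p = tmp_path / "m.pwm"
        write_pwm(pwm, p)
        back = read_pwm(p)
        assert np.allclose(back.matrix, pwm.matrix)

    def test_snp_table_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"rsid": ["rs1"], "chrom": ["chr6"], "pos": [117_000_000],
             "ref": ["C"], "alt": ["T"], "risk_allele": ["T"], "is_tag": [True]}
        )
        p = tmp_path / "snps.tsv"
        df.to_csv(p, sep="\t", index=False)
        back = read_snp_table(p)
        assert back.loc[0, "risk_allele"] == "T"

    def test_vcf_positions_converted_to_0_based(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\n"
            "chr6\t117210052\trs_example\tC\tT\n"
        )
        back = read_vcf_snps(p)
        assert back.loc[0, "pos"] == 117210051
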