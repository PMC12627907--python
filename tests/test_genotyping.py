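"""Allele counting, genotype calls, concordance and the allelic-bias test."""

import numpy as np
import pytest
from scipy import stats

from capqc.alignments import ReadRecord
from capqc.genotyping import (AlleleCounts, GenotypingError, bias_test_by_class,
                              bonferroni_adjust, call_genotype, classify_variant,
                              concordance, pileup_allele_counts,
                              quasibinomial_bias_test)
from capqc.panels import SNPSite
from capqc.simulate import simulate_allele_counts

SITE = SNPSite("chr1", 101, "A", "G", "s1")


def _ac(site=SITE, **depths):
    ac = AlleleCounts(site)
    for b, d in depths.items():
        ac.depth[b] = d
    return ac


def _read(seq, start=0, mapq=37, qual=40, dup=False, name="r"):
    return ReadRecord(name, True, "chr1", start, start + len(seq), seq,
                      qualities=tuple([qual] * len(seq)), mapq=mapq,
                      duplicate=dup)


class TestPileup:
    def test_counts_at_site(self):
        reads = [_read("A" * 10, start=95, name=f"a{i}") for i in range(5)]
        reads += [_read("G" * 10, start=95, name=f"g{i}") for i in range(3)]
        counts = pileup_allele_counts(reads, [SITE])
        assert counts["s1"].depth == {"A": 5, "C": 0, "G": 3, "T": 0}
        assert counts["s1"].total_depth == 8

    @pytest.mark.parametrize("kwargs", [
        {"mapq": 10}, {"qual": 10}, {"dup": True},
    ])
    def test_filters_exclude_reads(self, kwargs):
        reads = [_read("A" * 10, start=95), _read("A" * 10, start=95, **kwargs)]
        counts = pileup_allele_counts(reads, [SITE])
        assert counts["s1"].depth["A"] == 1

    def test_uncovered_site_present_with_zero(self):
        counts = pileup_allele_counts([], [SITE])
        assert counts["s1"].total_depth == 0


class TestGenotyper:
    def test_het_call(self):
        call = call_genotype(_ac(A=5, G=3))
        assert call.alleles == frozenset("AG") and call.depth == 8

    def test_below_min_depth_absent(self):
        assert call_genotype(_ac(A=2)) is None

    def test_minor_allele_filtered(self):
        call = call_genotype(_ac(A=9, G=1))
        assert call.alleles == frozenset("A")

    def test_multiallelic_truncated_to_top_two(self):
        call = call_genotype(_ac(A=10, G=8, C=5))
        assert call.alleles == frozenset("AG") and call.multiallelic


class TestConcordance:
    def _call(self, alleles, site=SITE):
        from capqc.genotyping import GenotypeCall
        return GenotypeCall(site, frozenset(alleles), 10)

    def test_shared_allele_is_match(self):
        pct, n = concordance({"s1": self._call("AG")}, {"s1": self._call("A")})
        assert pct == 100.0 and n == 1

    def test_disjoint_alleles_is_mismatch(self):
        pct, n = concordance({"s1": self._call("C")}, {"s1": self._call("AG")})
        assert pct == 0.0

    def test_empty_overlap_missing(self):
        pct, n = concordance({"s1": self._call("A")}, {"s2": self._call("A")})
        assert pct is None and n == 0

    def test_programmed_discordance_recovered(self, rng):
        """5% of enriched calls flipped to a foreign allele -> ~95% match."""
        n = 10_000
        base, enr = {}, {}
        for i in range(n):
            sid = f"s{i}"
            site = SNPSite("chr1", 10 * i + 1, "A", "G", sid)
            base[sid] = self._call("AG", site)
            enr[sid] = self._call("C" if rng.random() < 0.05 else "A", site)
        pct, _ = concordance(base, enr)
        assert pct == pytest.approx(95.0, abs=1.0)


class TestVariantClass:
    @pytest.mark.parametrize("a,b,label,transition", [
        ("G", "A", "AG", True), ("A", "G", "AG", True),
        ("C", "T", "CT", True), ("G", "T", "GT", False),
        ("A", "C", "AC", False), ("C", "G", "CG", False),
    ])
    def test_canonicalization(self, a, b, label, transition):
        vc = classify_variant(a, b)
        assert vc.label == label
        assert vc.first_allele == label[0]
        assert vc.is_transition == transition

    def test_identical_alleles_rejected(self):
        with pytest.raises(GenotypingError):
            classify_variant("A", "A")


class TestQuasibinomialTest:
    def test_symmetric_null_gives_p_one(self):
        res = quasibinomial_bias_test([5, 6, 4], [10, 12, 8])
        assert res.est_ad_ratio == 0.5
        assert res.p_value == pytest.approx(1.0)

    def test_boundary_flag(self):
        res = quasibinomial_bias_test([10, 12, 8], [10, 12, 8])
        assert res.boundary and res.est_ad_ratio < 1.0

    def test_single_site_dispersion_fixed(self):
        res = quasibinomial_bias_test([7], [10])
        assert res.dispersion == 1.0

    def test_ratio_reflection_and_permutation_invariance(self, rng):
        k = rng.integers(0, 10, size=30)
        n = k + rng.integers(1, 10, size=30)
        res = quasibinomial_bias_test(k, n)
        perm = rng.permutation(30)
        res_p = quasibinomial_bias_test(k[perm], n[perm])
        assert res_p.est_ad_ratio == res.est_ad_ratio
        assert res_p.p_value == pytest.approx(res.p_value)
        res_r = quasibinomial_bias_test(n - k, n)
        assert res_r.est_ad_ratio == pytest.approx(1 - res.est_ad_ratio)
        assert res_r.p_value == pytest.approx(res.p_value)

    def test_matches_statsmodels_quasibinomial(self, rng):
        """Estimate, dispersion and Wald statistic agree with an
        independent GLM fit on 50 random instances."""
        import statsmodels.api as sm
        for _ in range(50):
            m = int(rng.integers(2, 40))
            n = rng.integers(3, 31, size=m)
            k = rng.binomial(n, rng.uniform(0.2, 0.8))
            if k.sum() == 0 or k.sum() == n.sum():
                continue
            res = quasibinomial_bias_test(k, n)
            glm = sm.GLM(k / n, np.ones(m), family=sm.families.Binomial(),
                         var_weights=n).fit(scale="X2")
            p_hat = 1 / (1 + np.exp(-glm.params[0]))
            assert res.est_ad_ratio == pytest.approx(p_hat, rel=1e-8)
            assert res.dispersion == pytest.approx(glm.scale, rel=1e-6)
            assert res.p_value == pytest.approx(
                2 * stats.t.sf(abs(glm.tvalues[0]), m - 1), rel=1e-6)

    def test_dispersion_one_reduces_to_binomial_wald(self, rng):
        """With phi forced to 1 the statistic equals the plain binomial
        intercept Wald statistic from statsmodels."""
        import statsmodels.api as sm
        for _ in range(10):
            m = int(rng.integers(2, 20))
            n = rng.integers(3, 31, size=m)
            k = rng.binomial(n, 0.6)
            if k.sum() in (0, n.sum()):
                continue
            res = quasibinomial_bias_test(k, n)
            glm = sm.GLM(k / n, np.ones(m), family=sm.families.Binomial(),
                         var_weights=n).fit()  # scale = 1
            t_mine = stats.t.isf(res.p_value / 2, m - 1) * np.sign(res.est_ad_ratio - 0.5)
            # rel 1e-4: statsmodels solves by IRLS, we use the closed form
            assert t_mine * np.sqrt(res.dispersion) == pytest.approx(
                glm.tvalues[0], rel=1e-4)


class TestBonferroni:
    def test_default_threshold(self):
        assert bonferroni_adjust([], 0.05, 18) == pytest.approx(0.0027778, abs=1e-7)

    def test_single_test_threshold_is_alpha(self):
        assert bonferroni_adjust([], 0.05, 1) == 0.05

    def test_raw_significant_but_not_adjusted(self):
        res = quasibinomial_bias_test([70, 65, 72], [100, 100, 100])
        res.p_value = 0.004  # force the illustrative threshold case
        bonferroni_adjust([res], 0.05, 18)
        assert res.significant_raw and not res.significant_bonferroni


class TestBiasByClass:
    def test_damage_leakage_biases_ct_class_upward(self, rng):
        """Hom-CC sites miscalled as CT hets push the CT allele-depth
        ratio above 0.5 (first allele C over-represented ... actually the
        reference C dominates leaked T reads)."""
        sites = [SNPSite("chr1", 10 * i + 1, "C", "T", f"s{i}") for i in range(200)]
        counts, _ = simulate_allele_counts(
            sites, rng, mean_depth=20, het_fraction=0.0, damage_leakage=0.1)
        # treat the leaked sites as if called heterozygous C/T
        results = bias_test_by_class(counts.values(), min_depth=3)
        ct = next(r for r in results if r.variant_class == "CT")
        assert ct.est_ad_ratio > 0.5
        assert ct.significant_bonferroni

    def test_null_sites_unbiased(self, rng):
        sites = [SNPSite("chr1", 10 * i + 1, "A", "G", f"s{i}") for i in range(300)]
        counts, _ = simulate_allele_counts(sites, rng, mean_depth=15, ad_ratio=0.5)
        results = bias_test_by_class(counts.values(), min_depth=3)
        ag = next(r for r in results if r.variant_class == "AG")
        assert ag.est_ad_ratio == pytest.approx(0.5, abs=0.03)
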