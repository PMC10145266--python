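"""Pharmacogenetic statistics: carriers, HWE, haplotype EM/LD, group tests."""

import numpy as np
import pytest
from scipy import stats

from tacropk import (
    GenotypeRecord,
    ValidationError,
    classify_carriers,
    compare_groups,
    em_haplotypes,
    hwe_test,
    simulate_genotypes,
    spearman_scan,
)


def _rec(i, a5, a4):
    return GenotypeRecord(subject_id=f"S{i}", cyp3a5=a5, cyp3a4=a4)


class TestClassifyCarriers:
    @pytest.mark.parametrize(
        "a5,a4,expect5,expect4",
        [
            ("*1/*3", "*1/*1", "non-CYP3A5*3/*3", "CYP3A4*1/*1"),
            ("*3/*3", "*1/*1G", "CYP3A5*3/*3", "non-CYP3A4*1/*1"),
            ("*1/*1", "*1G/*1G", "non-CYP3A5*3/*3", "non-CYP3A4*1/*1"),
        ],
    )
    def test_binary_subclassification(self, a5, a4, expect5, expect4):
        c5, c4 = classify_carriers(_rec(1, a5, a4))
        assert (c5, c4) == (expect5, expect4)

    def test_unknown_genotype_string_rejected(self):
        with pytest.raises(ValidationError):
            GenotypeRecord("S1", "*2/*3", "*1/*1")
        with pytest.raises(ValidationError):
            GenotypeRecord("S1", "*1/*3", "*1G/*22")


class TestHWE:
    def test_exact_hwe_proportions_give_chi2_zero(self):
        res = hwe_test((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_cohort_scale_counts_match_hand_computation(self):
        # counts (1, 8, 5): allele freq 10/28, expecteds (1.79, 6.43, 5.79)
        res = hwe_test((1, 8, 5))
        assert res.expected == pytest.approx((1.7857, 6.4286, 5.7857), abs=1e-3)
        assert res.chi2 == pytest.approx(0.836, abs=0.005)
        assert res.method == "exact"  # smallest expected cell < 5
        assert res.p > 0.05
        chisq = hwe_test((1, 8, 5), method="chi-squared")
        assert chisq.p == pytest.approx(stats.chi2.sf(chisq.chi2, 1), rel=1e-12)
        assert chisq.p == pytest.approx(0.36, abs=0.01)

    def test_maximal_disequilibrium_detected_by_exact_test(self):
        res = hwe_test((10, 0, 10), method="exact")
        assert res.p < 0.01
        # expecteds (5, 10, 5) are well filled, so auto picks chi-squared,
        # which agrees on the verdict
        auto = hwe_test((10, 0, 10))
        assert auto.method == "chi-squared"
        assert auto.p < 0.01

    def test_monomorphic_sample_p_one(self):
        res = hwe_test((12, 0, 0))
        assert res.p == 1.0
        assert res.method == "monomorphic"

    def test_expecteds_sum_to_n_and_methods_agree_when_well_filled(self, rng):
        for _ in range(50):
            p = rng.uniform(0.25, 0.75)
            n = 400
            g = rng.multinomial(n, [p**2, 2 * p * (1 - p), (1 - p) ** 2])
            res_chi = hwe_test(tuple(g), method="chi-squared")
            res_ex = hwe_test(tuple(g), method="exact")
            assert sum(res_chi.expected) == pytest.approx(n)
            assert res_chi.chi2 >= 0
            if min(res_chi.expected) >= 10:
                # the exact null is discrete and conservative, so away from
                # the tail the two p-values can differ visibly; the exact p
                # never undercuts the asymptotic one by more than 0.05, and
                # in the tail the two agree closely
                assert res_ex.p >= res_chi.p - 0.05
                if res_chi.p < 0.1:
                    assert abs(res_chi.p - res_ex.p) < 0.05

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_test((-1, 2, 3))


class TestEMHaplotypes:
    def test_no_double_heterozygotes_reduces_to_counting(self):
        # phase is unambiguous: EM must equal direct haplotype counting
        records = (
            [_rec(i, "*1/*3", "*1/*1") for i in range(4)]        # *1-*1 / *3-*1
            + [_rec(10 + i, "*3/*3", "*1/*1G") for i in range(2)]  # *3-*1G / *3-*1
            + [_rec(20 + i, "*3/*3", "*1/*1") for i in range(4)]   # *3-*1 x2
        )
        res = em_haplotypes(records)
        # 20 haplotypes: *1-*1G: 0, *1-*1: 4, *3-*1G: 2, *3-*1: 14
        assert res.hap_freqs == pytest.approx((0.0, 0.2, 0.1, 0.7), abs=1e-6)

    def test_complete_ld_double_homozygotes(self):
        records = [_rec(i, "*1/*1", "*1G/*1G") for i in range(5)] + [
            _rec(10 + i, "*3/*3", "*1/*1") for i in range(5)
        ]
        res = em_haplotypes(records)
        assert res.hap_freqs == pytest.approx((0.5, 0.0, 0.0, 0.5), abs=1e-9)
        assert res.d_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_recovers_known_haplotype_frequencies(self):
        true = (0.4, 0.3, 0.2, 0.1)
        records = simulate_genotypes(10_000, true, seed=99)
        res = em_haplotypes(records)
        assert res.hap_freqs == pytest.approx(true, abs=0.02)

    def test_loglikelihood_nondecreasing(self):
        records = simulate_genotypes(200, (0.35, 0.15, 0.2, 0.3), seed=5)
        res = em_haplotypes(records)
        path = np.asarray(res.loglik_path)
        assert np.all(np.diff(path) >= -1e-9)

    def test_zero_haplotype_class_gives_dprime_one(self):
        records = simulate_genotypes(300, (6 / 28, 4 / 28, 0.0, 18 / 28), seed=21)
        res = em_haplotypes(records)
        assert res.polymorphic
        assert res.d_prime == pytest.approx(1.0, abs=1e-6)

    def test_monomorphic_locus_flagged(self):
        records = [_rec(i, "*3/*3", g) for i, g in enumerate(["*1/*1", "*1/*1G", "*1G/*1G"])]
        res = em_haplotypes(records)
        assert not res.polymorphic
        assert res.d_prime is None and res.r2 is None


class TestCompareGroups:
    def test_identical_log_means_give_small_f(self):
        values = [2.0, 4.0, 8.0, 2.0, 4.0, 8.0]
        groups = ["a", "a", "a", "b", "b", "b"]
        f, p = compare_groups(values, groups)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_two_group_anova_equals_squared_t(self, rng):
        x = rng.lognormal(1.0, 0.5, 12)
        g = np.array(["a"] * 5 + ["b"] * 7)
        f, p = compare_groups(x, g)
        t, p_t = stats.ttest_ind(np.log(x[g == "a"]), np.log(x[g == "b"]))
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(p_t, rel=1e-10)

    def test_scale_invariance_on_log_scale(self, rng):
        x = rng.lognormal(0.5, 0.4, 20)
        g = np.array(["a", "b"] * 10)
        f1, _ = compare_groups(x, g)
        f2, _ = compare_groups(1000 * x, g)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_fivefold_separation_detected_at_cohort_scale(self):
        # genotype-class geometric means 3.37 vs 18.13 with gsd ~1.6, n=(5,9)
        rng = np.random.default_rng(14)
        a = 3.37 * np.exp(rng.normal(0, np.log(1.54), 5))
        b = 18.13 * np.exp(rng.normal(0, np.log(1.65), 9))
        _, p = compare_groups(
            np.concatenate([a, b]), np.array(["c"] * 5 + ["n"] * 9)
        )
        assert p < 0.001

    def test_small_group_rejected_with_name(self):
        with pytest.raises(ValidationError, match="tiny"):
            compare_groups([1.0, 2.0, 3.0], ["tiny", "big", "big"])


class TestSpearmanScan:
    def test_identity_and_monotone_transforms(self):
        import pandas as pd

        param = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        cov = pd.DataFrame({"same": param, "inv": 1.0 / param, "const": np.ones(5)})
        out = spearman_scan(cov, param).set_index("covariate")
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["inv", "rho"] == pytest.approx(-1.0)
        assert np.isnan(out.loc["const", "rho"])
        assert out.loc["const", "note"] == "constant covariate"

    def test_type_one_error_calibrated_under_permutation(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        n, reps = 20, 2000
        param = rng.normal(size=n)
        hits = 0
        for _ in range(reps):
            cov = pd.DataFrame({"x": rng.permutation(param)})
            p = spearman_scan(cov, param)["p"].iloc[0]
            hits += p < 0.05
        assert 0.035 < hits / reps < 0.065
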