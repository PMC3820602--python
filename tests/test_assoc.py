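import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from transgwas.assoc import (
    DegeneratePredictorError,
    hwe_test,
    linear_assoc,
    logistic_assoc,
    snp_qc_filter,
)
from transgwas.io_formats import SummaryStatRecord
from transgwas.synthetic_data import simulate_quantitative_cohort


class TestLinearAssoc:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.4, 200).astype(float)
        res = linear_assoc(dosage, 2.0 * dosage)
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.p < 1e-100

    def test_recovers_simulated_effect(self):
        dosage, pheno = simulate_quantitative_cohort(5000, 0.3, 0.04, 0.4, seed=11)
        res = linear_assoc(dosage, pheno["hba1c"], pheno[["age", "sex"]])
        assert abs(res.beta - 0.04) < 3 * res.se
        assert res.covariates_used == ["age", "sex"]
        assert res.n == 5000

    def test_matches_closed_form_simple_regression(self):
        rng = np.random.default_rng(1)
        dosage = rng.binomial(2, 0.3, 500).astype(float)
        trait = 5.7 + 0.05 * dosage + rng.normal(0, 0.4, 500)
        res = linear_assoc(dosage, trait)
        slope = np.cov(dosage, trait)[0, 1] / np.var(dosage, ddof=1)
        assert res.beta == pytest.approx(slope, abs=1e-8)

    def test_permutation_null_p_values_uniform(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.3, 120).astype(float)
        trait = rng.normal(5.7, 0.4, 120)
        pvals = []
        for _ in range(500):
            perm = rng.permutation(trait)
            pvals.append(linear_assoc(dosage, perm).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_dosage_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            linear_assoc(np.ones(100), np.random.default_rng(3).normal(size=100))

    def test_rows_with_missing_values_deleted(self):
        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, 0.4, 100).astype(float)
        trait = rng.normal(size=100)
        trait[:10] = np.nan
        assert linear_assoc(dosage, trait).n == 90


class TestLogisticAssoc:
    def test_null_odds_ratio_near_one(self):
        rng = np.random.default_rng(5)
        dosage = rng.binomial(2, 0.4, 2000).astype(float)
        outcome = rng.integers(0, 2, 2000)
        res = logistic_assoc(dosage, outcome)
        assert abs(res.beta) < 3 * res.se
        lo, hi = res.ci95
        assert lo < res.or_ < hi

    def test_matches_2x2_cross_product_without_covariates(self):
        rng = np.random.default_rng(6)
        carrier = rng.integers(0, 2, 1000).astype(float)
        p_case = np.where(carrier > 0, 0.4, 0.25)
        case = (rng.random(1000) < p_case).astype(float)
        a = ((carrier > 0) & (case > 0)).sum()
        b = ((carrier > 0) & (case == 0)).sum()
        c = ((carrier == 0) & (case > 0)).sum()
        d = ((carrier == 0) & (case == 0)).sum()
        assert min(a, b, c, d) >= 5
        res = logistic_assoc(carrier, case)
        assert res.or_ == pytest.approx((a * d) / (b * c), rel=0.15)

    def test_complete_separation_flagged_not_raised(self):
        dosage = np.array([0.0] * 20 + [2.0] * 20)
        outcome = np.array([0.0] * 20 + [1.0] * 20)
        res = logistic_assoc(dosage, outcome)
        assert res.separation
        assert np.isnan(res.beta)

    def test_single_outcome_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            logistic_assoc(np.array([0.0, 1, 2, 1]), np.ones(4))


class TestTypeIError:
    def test_both_tests_hold_nominal_level(self):
        rng = np.random.default_rng(7)
        n, reps, alpha = 1000, 2000, 0.05
        rej_lin = rej_log = 0
        for _ in range(reps):
            dosage = rng.binomial(2, 0.3, n).astype(float)
            trait = rng.normal(5.7, 0.4, n)
            if linear_assoc(dosage, trait).p <= alpha:
                rej_lin += 1
        for _ in range(reps):
            dosage = rng.binomial(2, 0.3, n).astype(float)
            outcome = (rng.random(n) < 0.2).astype(float)
            r = logistic_assoc(dosage, outcome)
            if not r.separation and r.p <= alpha:
                rej_log += 1
        assert 0.04 <= rej_lin / reps <= 0.06
        assert 0.04 <= rej_log / reps <= 0.06


class TestHweExact:
    def test_equilibrium_proportions_give_p_one(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_total_heterozygote_deficit_fails_qc_threshold(self):
        assert hwe_test((50, 0, 50)) < 1e-6

    def test_monomorphic_site_is_p_one(self):
        assert hwe_test((100, 0, 0)) == 1.0

    def test_matches_brute_force_enumeration(self):
        # independent oracle: enumerate all (n_AA, n_Aa, n_aa) with the same
        # allele counts and sum multinomial-conditional probabilities
        import math

        def brute(n_aa, n_ab, n_bb):
            n = n_aa + n_ab + n_bb
            na = 2 * n_aa + n_ab

            # conditional pmf of the heterozygote count given allele counts
            def pmf(h):
                paa = (na - h) // 2
                pbb = n - paa - h
                if (na - h) % 2 or paa < 0 or pbb < 0:
                    return 0.0
                return (
                    math.factorial(n)
                    / (math.factorial(paa) * math.factorial(h) * math.factorial(pbb))
                    * 2**h
                    / (math.factorial(2 * n) // (math.factorial(na) * math.factorial(2 * n - na)))
                )

            probs = [pmf(h) for h in range(0, min(na, 2 * n - na) + 1)]
            tot = sum(probs)
            obs = probs[n_ab] / tot
            return sum(p / tot for p in probs if p / tot <= obs * (1 + 1e-12))

        for counts in [(5, 10, 5), (8, 2, 10), (3, 7, 0), (12, 1, 2)]:
            assert hwe_test(counts) == pytest.approx(brute(*counts), rel=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    def test_symmetric_in_allele_labels(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_test((a, b, c)) == pytest.approx(hwe_test((c, b, a)), rel=1e-12)


def _rec(snp_id, eaf=0.3, **kw):
    return SummaryStatRecord(snp_id, "1", 100, "A", "G", eaf, 0.01, 0.5, 1000, **kw)


class TestQcFilter:
    def test_each_rule_removes_its_violator(self):
        records = [
            _rec("maf_hi", eaf=0.995),
            _rec("maf_lo", eaf=0.005),
            _rec("miss", missing_rate=0.10),
            _rec("hwe", hwe_p=1e-7),
            _rec("info", info=0.4),
            _rec("multi", eaf=0.004, missing_rate=0.2),
            _rec("clean", missing_rate=0.01, hwe_p=0.5, info=0.9),
        ]
        kept, counts = snp_qc_filter(records)
        assert [r.snp_id for r in kept] == ["clean"]
        assert counts == {"maf": 3, "missing": 2, "hwe": 1, "info": 1}

    def test_boundaries_follow_stated_inequalities(self):
        kept, _ = snp_qc_filter([
            _rec("info_boundary", info=0.5),       # ">= 0.5" retained
            _rec("maf_boundary", eaf=0.01),        # MAF "< 1%" removed: 0.01 kept
            _rec("miss_boundary", missing_rate=0.05),  # "> 5%" removed: 0.05 kept
            _rec("hwe_boundary", hwe_p=1e-6),      # "<= 1e-6" removed
        ])
        assert [r.snp_id for r in kept] == ["info_boundary", "maf_boundary", "miss_boundary"]

    def test_absent_info_treated_as_genotyped(self):
        kept, counts = snp_qc_filter([_rec("genotyped")])
        assert len(kept) == 1 and counts["info"] == 0
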