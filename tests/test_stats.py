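"""Burden, HWE, prevalence, concordance and Z-test statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from fmrscreen import (
    CallMode,
    ContingencyTable2x2,
    PrevalenceRow,
    PrevalenceSummary,
    RangeClass,
    Sex,
    burden_from_counts,
    callset_concordance,
    compare_prevalence,
    fisher_burden,
    hwe_female_chi2,
    hwe_from_genotypes,
    parental_age_ztest,
    summarize_prevalence,
)
from fmrscreen import datasets
from conftest import make_genotype


def fisher_p_oracle(a, b, c, d):
    """Exact two-sided Fisher p by enumerating all tables with the observed
    margins (hypergeometric probabilities as exact fractions)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)


class TestFisherBurden:
    @pytest.mark.parametrize(
        "table,expected_or",
        [
            ((13, 2042, 8, 897), 0.71),
            ((6, 315, 11, 997), 1.73),
            ((16, 2481, 4, 1123), 1.81),
            ((7, 607, 10, 1126), 1.30),
            ((29, 4523, 12, 2020), 1.08),
            ((13, 922, 21, 2123), 1.43),
        ],
    )
    def test_cross_product_odds_ratios(self, table, expected_or):
        r = burden_from_counts(*table)
        assert round(r.odds_ratio, 2) == expected_or

    def test_identical_rows_give_or_one_p_one(self):
        r = burden_from_counts(5, 95, 5, 95)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_cell_flags_odds_ratio(self):
        assert math.isinf(burden_from_counts(5, 95, 0, 100).odds_ratio)
        assert burden_from_counts(0, 100, 5, 95).odds_ratio == 0.0
        assert not burden_from_counts(5, 95, 0, 100).odds_ratio_defined

    def test_zero_margin_gives_p_one(self):
        assert burden_from_counts(0, 100, 0, 50).p_value == 1.0

    def test_p_matches_enumeration_oracle_small_tables(self):
        """Spot sweep: all tables with total <= 12 (full sweep in the
        acceptance suite)."""
        total = 12
        for a in range(total + 1):
            for b in range(total + 1 - a):
                for c in range(total + 1 - a - b):
                    for d in range(total + 1 - a - b - c):
                        if a + b + c + d == 0:
                            continue
                        r = fisher_burden(ContingencyTable2x2(a, b, c, d))
                        oracle = float(fisher_p_oracle(a, b, c, d))
                        assert r.p_value == pytest.approx(oracle, abs=1e-10)

    def test_or_invariance_under_table_symmetries(self):
        r = burden_from_counts(7, 13, 4, 21)
        # swap both rows and both columns: OR unchanged
        r_sym = burden_from_counts(21, 4, 13, 7)
        assert r_sym.odds_ratio == pytest.approx(r.odds_ratio)
        # swap rows only: OR inverts
        r_swap = burden_from_counts(4, 21, 7, 13)
        assert r_swap.odds_ratio == pytest.approx(1.0 / r.odds_ratio)

    def test_compare_prevalence_zero_cell_contract(self):
        r = compare_prevalence(42, 2365, 0, 500)
        assert math.isinf(r.odds_ratio) and 0 < r.p_value < 1

    def test_compare_prevalence_identical_pairs(self):
        assert compare_prevalence(5, 100, 5, 100).p_value == pytest.approx(1.0)


class TestHWE:
    def test_ssc_female_counts(self):
        r = hwe_female_chi2(n_het=59, n_hom_carrier=0, n_females=3694)
        assert round(r.chi2, 2) == 0.24
        assert round(r.p_value, 2) == 0.89

    def test_spark_female_counts(self):
        r = hwe_female_chi2(n_het=39, n_hom_carrier=0, n_females=4827)
        assert round(r.chi2, 2) == 0.08
        assert round(r.p_value, 2) == 0.96

    def test_exact_hw_proportions_give_chi2_zero(self):
        # 3200 p^2 / 1600 2pq / 200 q^2 with q = 0.2, n = 3200+1600+200... use
        # q=0.2, n=5000: expected 3200/1600/200 exactly
        r = hwe_female_chi2(n_het=1600, n_hom_carrier=200, n_females=5000)
        assert r.chi2 == pytest.approx(0.0, abs=1e-9)
        assert r.p_value == pytest.approx(1.0)

    def test_scale_consistency(self):
        """Multiplying all observed counts by k multiplies chi-square by k."""
        r1 = hwe_female_chi2(30, 2, 1000)
        r5 = hwe_female_chi2(150, 10, 5000)
        assert r5.chi2 == pytest.approx(5 * r1.chi2)

    def test_df_configurable(self):
        r1 = hwe_female_chi2(59, 0, 3694, df=1)
        r2 = hwe_female_chi2(59, 0, 3694, df=2)
        assert r1.chi2 == r2.chi2
        assert r1.p_value < r2.p_value

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hwe_female_chi2(1, 0, 0)
        with pytest.raises(ValueError):
            hwe_female_chi2(60, 50, 100)

    def test_mean_chi2_near_df_under_null(self):
        """Genotypes simulated under HWE give mean chi2 ~ 1 over seeds.

        With the allele frequency estimated from the same data, the Pearson
        statistic has 1 degree of freedom (3 classes - 1 - 1 estimated
        parameter), so its null mean is 1 regardless of the df convention
        used for the reported p-value.
        """
        q, n = 0.05, 2000
        chis = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            alleles = rng.random((n, 2)) < q
            n_het = int((alleles.sum(axis=1) == 1).sum())
            n_hom = int((alleles.sum(axis=1) == 2).sum())
            chis.append(hwe_female_chi2(n_het, n_hom, n).chi2)
        # chi2(1) has variance 2; 4 standard errors of the 50-seed mean
        assert np.mean(chis) == pytest.approx(1.0, abs=4 * math.sqrt(2 / 50))

    def test_hwe_from_genotypes_counts_carriers(self):
        genos = [
            make_genotype("f1", Sex.FEMALE, (29, 70)),
            make_genotype("f2", Sex.FEMALE, (29, 30)),
            make_genotype("f3", Sex.FEMALE, (60, 70)),
            make_genotype("m1", Sex.MALE, (70,)),  # males excluded
        ]
        r = hwe_from_genotypes(genos)
        assert (r.n_females, r.n_het, r.n_hom_carrier) == (3, 1, 1)


class TestParentalAgeZTest:
    def test_identical_groups(self):
        z, p = parental_age_ztest([30, 35, 40], [30, 35, 40])
        assert z == 0.0 and p == 1.0

    def test_large_separation(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(30, 1, 200)
        g2 = rng.normal(45, 1, 200)
        _, p = parental_age_ztest(g1, g2)
        assert p < 1e-12

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            parental_age_ztest([30], [30, 31])

    def test_p_uniform_under_null(self):
        """1000 null replicates: p-values pass a KS test for uniformity."""
        rng = np.random.default_rng(7)
        pvals = [
            parental_age_ztest(rng.normal(35, 5, 60), rng.normal(35, 5, 60))[1]
            for _ in range(1000)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestPrevalence:
    def test_all_printed_percentage_cells(self):
        """All twelve per-role percentage cells follow from the counts."""
        expected_ssc = {
            "father": 0.93, "mother": 1.78, "male_proband": 0.63,
            "male_sibling": 0.88, "female_proband": 1.87, "female_sibling": 1.09,
        }
        expected_spark = {
            "father": 0.62, "mother": 0.71, "male_proband": 0.64,
            "male_sibling": 0.35, "female_proband": 1.14, "female_sibling": 0.88,
        }
        for counts, expected in (
            (datasets.SSC_ROLE_COUNTS, expected_ssc),
            (datasets.SPARK_ROLE_COUNTS, expected_spark),
        ):
            summary = PrevalenceSummary.from_role_counts(counts)
            for role, pct in expected.items():
                assert round(summary.rows[role].percent, 2) == pct

    def test_pooled_offspring_rows(self):
        ssc = PrevalenceSummary.from_role_counts(datasets.SSC_ROLE_COUNTS)
        assert round(ssc.rows["male_offspring"].percent, 2) == 0.71
        assert round(ssc.rows["female_offspring"].percent, 2) == 1.28
        spark = PrevalenceSummary.from_role_counts(datasets.SPARK_ROLE_COUNTS)
        assert round(spark.rows["male_offspring"].percent, 2) == 0.55
        assert round(spark.rows["female_offspring"].percent, 2) == 0.97

    def test_zero_carriers(self):
        row = PrevalenceRow(100, 100, 0)
        assert row.percent == 0.0

    def test_zero_genotyped_percent_missing(self):
        assert PrevalenceRow(5, 0, 0).percent is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            PrevalenceRow(10, 20, 5)

    def test_summarize_from_genotypes_excludes_no_calls(self, trio_family):
        from fmrscreen import RepeatGenotype
        from fmrscreen.pipeline import family_roles

        genos = {
            "fa": make_genotype("fa", Sex.MALE, (70,)),
            "mo": RepeatGenotype("mo", "FMR1", Sex.FEMALE, ()),  # no-call
            "pro": make_genotype("pro", Sex.MALE, (30,)),
        }
        summary = summarize_prevalence(genos, family_roles({"f": trio_family}))
        assert summary.rows["mother"].processed == 1
        assert summary.rows["mother"].genotyped == 0
        assert summary.rows["father"].carriers == 1
        assert summary.rows["total"].genotyped == 2


class TestConcordance:
    def test_validation_table_flags(self):
        """Off-target WGS calls flag 7 expanded samples; PCR confirms none,
        with 3 of the 7 in the gray zone by PCR."""
        a = datasets.validation_genotypes(CallMode.EH_OFFTARGET)
        b = datasets.validation_genotypes(CallMode.PCR)
        summary = callset_concordance(a, b)
        assert len(summary.records) == 16
        assert summary.n_flagged_a == 7
        assert summary.n_flagged_b == 0
        assert summary.count_b_class_among_flagged_a(RangeClass.GRAY) == 3
        assert summary.count_b_class_among_flagged_a(RangeClass.PREMUTATION) == 0

    def test_identical_call_sets_concordant(self):
        calls = datasets.validation_genotypes(CallMode.PCR)
        summary = callset_concordance(calls, calls)
        assert summary.n_class_discordant == 0

    def test_region_only_reduces_flags(self):
        a = datasets.validation_genotypes(CallMode.EH_OFFTARGET)
        b = datasets.validation_genotypes(CallMode.EH_REGION_ONLY)
        summary = callset_concordance(a, b)
        assert summary.n_flagged_b <= summary.n_flagged_a

    def test_unmatched_samples_excluded_with_warning(self, caplog):
        a = [make_genotype("s1", Sex.MALE, (30,)), make_genotype("s2", Sex.MALE, (30,))]
        b = [make_genotype("s1", Sex.MALE, (30,))]
        with caplog.at_level("WARNING"):
            summary = callset_concordance(a, b)
        assert len(summary.records) == 1
        assert any("only one call set" in m for m in caplog.messages)
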