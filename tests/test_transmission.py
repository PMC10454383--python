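"""Parental-origin assignment and transmission categorization."""

import itertools

import pytest

from fmrscreen import (
    FamilyRole,
    Origin,
    QCFlag,
    Sex,
    TransmissionCategory,
    TransmissionSummary,
    assign_parental_origin,
    classify_transmissions,
    summarize_transmissions,
)
from conftest import make_genotype, make_trio_family


def exhaustive_daughter_partition(daughter, father_allele, mother_alleles):
    """Oracle: score both (paternal, maternal) partitions exhaustively."""
    best = None
    for pat, mat in itertools.permutations(daughter, 2):
        for m in mother_alleles:
            cost = abs(pat - father_allele) + abs(mat - m)
            cand = (cost, pat, mat, m)
            if best is None or cand[0] < best[0]:
                best = cand
    return best


class TestAssignParentalOrigin:
    def test_son_matches_nearest_maternal_allele(self):
        son = make_genotype("pro", Sex.MALE, (48,))
        mother = make_genotype("mo", Sex.FEMALE, (29, 48))
        father = make_genotype("fa", Sex.MALE, (23,))
        (a,) = assign_parental_origin(son, father, mother)
        assert a.origin is Origin.MATERNAL
        assert a.parent_allele == 48 and a.delta == 0
        assert not a.flags

    def test_daughter_partition_exact_match(self):
        daughter = make_genotype("pro", Sex.FEMALE, (27, 30))
        father = make_genotype("fa", Sex.MALE, (27,))
        mother = make_genotype("mo", Sex.FEMALE, (29, 30))
        mat, pat = sorted(
            assign_parental_origin(daughter, father, mother),
            key=lambda a: a.origin.value,  # "maternal" sorts before "paternal"
        )
        assert mat.origin is Origin.MATERNAL and mat.offspring_allele == 30 and mat.delta == 0
        assert pat.origin is Origin.PATERNAL and pat.offspring_allele == 27 and pat.delta == 0

    def test_poor_match_flagged(self):
        son = make_genotype("pro", Sex.MALE, (80,))
        mother = make_genotype("mo", Sex.FEMALE, (29, 30))
        father = make_genotype("fa", Sex.MALE, (23,))
        (a,) = assign_parental_origin(son, father, mother)
        assert a.parent_allele == 30 and a.delta == 50
        assert QCFlag.POOR_MATCH in a.flags

    def test_son_never_assigned_paternal(self):
        """A son's allele goes to the mother even if the father matches better."""
        son = make_genotype("pro", Sex.MALE, (60,))
        mother = make_genotype("mo", Sex.FEMALE, (29, 30))
        father = make_genotype("fa", Sex.MALE, (60,))
        (a,) = assign_parental_origin(son, father, mother)
        assert a.origin is Origin.MATERNAL

    def test_ambiguous_tie_flagged(self):
        son = make_genotype("pro", Sex.MALE, (30,))
        mother = make_genotype("mo", Sex.FEMALE, (29, 31))
        father = make_genotype("fa", Sex.MALE, (23,))
        (a,) = assign_parental_origin(son, father, mother)
        assert QCFlag.AMBIGUOUS_MATCH in a.flags
        assert a.parent_allele == 29  # tie breaks to the smaller allele

    @pytest.mark.parametrize(
        "daughter,father_allele,mother_alleles",
        [
            ((27, 30), 27, (29, 30)),
            ((30, 85), 85, (29, 30)),
            ((29, 48), 23, (29, 48)),
            ((33, 71), 30, (30, 33)),
            ((28, 40), 29, (38, 41)),
        ],
    )
    def test_daughter_partition_matches_exhaustive_oracle(
        self, daughter, father_allele, mother_alleles
    ):
        gt = make_genotype("d", Sex.FEMALE, daughter)
        fa = make_genotype("fa", Sex.MALE, (father_allele,))
        mo = make_genotype("mo", Sex.FEMALE, mother_alleles)
        assignments = assign_parental_origin(gt, fa, mo)
        cost = sum(abs(a.delta) for a in assignments)
        oracle_cost = exhaustive_daughter_partition(daughter, father_allele, mother_alleles)[0]
        assert cost == oracle_cost


def run_family(genos, proband_sex=Sex.MALE, sibling_sex=None):
    fam = make_trio_family(proband_sex=proband_sex, sibling_sex=sibling_sex)
    return fam, classify_transmissions(fam, genos)


class TestClassifyTransmissions:
    def test_paternal_premutation_to_daughter(self):
        genos = {
            "fa": make_genotype("fa", Sex.MALE, (85,)),
            "mo": make_genotype("mo", Sex.FEMALE, (29, 30)),
            "pro": make_genotype("pro", Sex.FEMALE, (30, 85)),
        }
        _, calls = run_family(genos, proband_sex=Sex.FEMALE)
        by_allele = {c.offspring_allele: c for c in calls}
        assert by_allele[85].category is TransmissionCategory.PREMUTATION_TRANSMITTED
        assert by_allele[85].origin is Origin.PATERNAL
        assert by_allele[30].category is TransmissionCategory.NORMAL
        assert by_allele[30].origin is Origin.MATERNAL

    def test_normal_allele_from_carrier_mother(self):
        genos = {
            "fa": make_genotype("fa", Sex.MALE, (30,)),
            "mo": make_genotype("mo", Sex.FEMALE, (29, 98)),
            "pro": make_genotype("pro", Sex.MALE, (29,)),
        }
        _, calls = run_family(genos)
        (c,) = calls
        assert c.category is TransmissionCategory.NORMAL_FROM_CARRIER
        assert c.origin is Origin.MATERNAL and c.delta == 0

    def test_de_novo_expansion_in_son(self):
        genos = {
            "fa": make_genotype("fa", Sex.MALE, (30,)),
            "mo": make_genotype("mo", Sex.FEMALE, (29, 30)),
            "pro": make_genotype("pro", Sex.MALE, (80,)),
        }
        _, calls = run_family(genos)
        (c,) = calls
        assert c.category is TransmissionCategory.DE_NOVO
        assert c.origin is Origin.DE_NOVO and c.delta == 50

    def test_contraction_flagged_as_normal_from_carrier(self):
        genos = {
            "fa": make_genotype("fa", Sex.MALE, (30,)),
            "mo": make_genotype("mo", Sex.FEMALE, (29, 60)),
            "pro": make_genotype("pro", Sex.MALE, (52,)),
        }
        _, calls = run_family(genos)
        (c,) = calls
        assert c.category is TransmissionCategory.NORMAL_FROM_CARRIER
        assert QCFlag.CONTRACTION in c.qc_flags

    def test_x_linkage_violation_flagged(self):
        """A son's expanded allele explainable only paternally is flagged."""
        genos = {
            "fa": make_genotype("fa", Sex.MALE, (85,)),
            "mo": make_genotype("mo", Sex.FEMALE, (29, 30)),
            "pro": make_genotype("pro", Sex.MALE, (85,)),
        }
        fam, calls = run_family(genos)
        (c,) = calls
        assert QCFlag.X_LINKAGE_VIOLATION in c.qc_flags
        summary = summarize_transmissions(calls, {fam.family_id: fam}, genos)
        assert summary.n_x_violations == 1
        assert summary.n_premutation_transmitted == 0
        assert summary.n_de_novo == 0

    def test_missing_parent_genotype_skips_family(self, caplog):
        genos = {
            "fa": make_genotype("fa", Sex.MALE, (30,)),
            "pro": make_genotype("pro", Sex.MALE, (29,)),
        }
        fam = make_trio_family()
        with caplog.at_level("WARNING"):
            assert classify_transmissions(fam, genos) == []
        assert any("missing parental genotype" in m for m in caplog.messages)


class TestSummarize:
    def test_father_to_son_premutation_is_structurally_zero(self):
        """No call path can produce a father-to-son transmission on chrX."""
        genos = {
            "fa": make_genotype("fa", Sex.MALE, (85,)),
            "mo": make_genotype("mo", Sex.FEMALE, (29, 90)),
            "pro": make_genotype("pro", Sex.MALE, (90,)),
            "sib": make_genotype("sib", Sex.FEMALE, (29, 85)),
        }
        fam = make_trio_family(sibling_sex=Sex.FEMALE)
        calls = classify_transmissions(fam, genos)
        summary = summarize_transmissions(calls, {fam.family_id: fam}, genos)
        for role in (FamilyRole.MALE_PROBAND, FamilyRole.MALE_SIBLING):
            for rng in ("premutation", "normal"):
                assert summary.counts[("father", role, rng)] == 0
        assert summary.counts[("mother", FamilyRole.MALE_PROBAND, "premutation")] == 1
        assert summary.counts[("father", FamilyRole.FEMALE_SIBLING, "premutation")] == 1

    def test_percentages_use_carrier_family_offspring_denominator(self):
        summary = TransmissionSummary(
            cohort_id="t",
            counts={("mother", FamilyRole.MALE_PROBAND, "premutation"): 10},
            de_novo_counts={},
            n_offspring_in_carrier_families=141,
            n_carrier_families=79,
        )
        assert summary.percentage(10) == pytest.approx(7.0922, abs=5e-3)

    def test_empty_cohort_reports_zero(self):
        summary = TransmissionSummary(
            cohort_id="t",
            counts={},
            de_novo_counts={},
            n_offspring_in_carrier_families=0,
            n_carrier_families=0,
        )
        assert summary.percentage(0) == 0.0
        frame = summary.to_frame()
        assert len(frame) == 20 and (frame["count"] == 0).all()

    def test_category_counts_partition_offspring_alleles(self):
        """Premutation-transmitted + de novo + non-inheriting never exceeds
        the number of offspring alleles in carrier families."""
        genos = {
            "fa": make_genotype("fa", Sex.MALE, (30,)),
            "mo": make_genotype("mo", Sex.FEMALE, (29, 98)),
            "pro": make_genotype("pro", Sex.MALE, (98,)),
            "sib": make_genotype("sib", Sex.MALE, (29,)),
        }
        fam = make_trio_family(sibling_sex=Sex.MALE)
        calls = classify_transmissions(fam, genos)
        summary = summarize_transmissions(calls, {fam.family_id: fam}, genos)
        total_alleles = 2  # two sons, one allele each
        assert (
            summary.n_premutation_transmitted
            + summary.n_de_novo
            + summary.n_noninheriting
            <= total_alleles
        )
        assert summary.n_premutation_transmitted == 1
        assert summary.n_noninheriting == 1
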