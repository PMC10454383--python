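"""Cohort-level statistics for repeat-expansion carrier screening.

Covers the standard battery for a family-based carrier screen:

* per-role carrier prevalence tables (processed / genotyped / carriers),
* sex-stratified Fisher exact burden tests comparing probands with
  unaffected same-sex siblings (carriers of at least one expanded allele
  vs non-carriers, counted per individual),
* Hardy-Weinberg equilibrium chi-square in females (diploid for chrX) as
  a genotyping quality-control check,
* two-cohort prevalence comparison (Fisher exact),
* a two-sample Z-test on parental ages, and
* call-set concordance between two genotyping modes (e.g. WGS-based
  calls vs PCR sizing), keyed on the longest-allele range class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import (
    CarrierStatus,
    LocusCatalog,
    RangeClass,
    classify_allele,
    classify_individual,
    default_catalog,
)
from .io import FamilyRole, RepeatGenotype

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fisher exact burden test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns carrier/non-carrier."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class BurdenResult:
    table: ContingencyTable2x2
    odds_ratio: float  # cross-product ad/bc; inf / 0.0 / nan on zero cells
    p_value: float
    method: str = "fisher_exact_two_sided"

    @property
    def odds_ratio_defined(self) -> bool:
        return math.isfinite(self.odds_ratio) and self.odds_ratio > 0


def fisher_burden(table: ContingencyTable2x2) -> BurdenResult:
    """Two-sided Fisher exact test with the sample cross-product odds ratio.

    The p-value sums hypergeometric probabilities not exceeding that of
    the observed table (the classic two-sided convention).  The odds
    ratio is the unconditional cross-product a*d / (b*c); zero cells make
    it 0, inf, or nan (flagged via ``odds_ratio_defined``).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        p = 1.0  # a zero margin admits only the observed table
    else:
        _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    ad, bc = a * d, b * c
    if bc == 0 and ad == 0:
        odds = float("nan")
    elif bc == 0:
        odds = float("inf")
    else:
        odds = ad / bc
    return BurdenResult(table=table, odds_ratio=odds, p_value=float(p))


def burden_from_counts(
    carriers_1: int, noncarriers_1: int, carriers_2: int, noncarriers_2: int
) -> BurdenResult:
    return fisher_burden(
        ContingencyTable2x2(carriers_1, noncarriers_1, carriers_2, noncarriers_2)
    )


def compare_prevalence(
    carriers_a: int, total_a: int, carriers_b: int, total_b: int
) -> BurdenResult:
    """Fisher exact comparison of two carrier prevalences."""
    if carriers_a > total_a or carriers_b > total_b:
        raise ValueError("carrier count exceeds cohort total")
    return burden_from_counts(
        carriers_a, total_a - carriers_a, carriers_b, total_b - carriers_b
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium in females
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HWEResult:
    n_females: int
    n_het: int
    n_hom_carrier: int
    allele_freq: float
    chi2: float
    df: int
    p_value: float
    expected: tuple[float, float, float]  # (non-carrier, het, hom carrier)


def hwe_female_chi2(
    n_het: int, n_hom_carrier: int, n_females: int, df: int = 2
) -> HWEResult:
    """Pearson chi-square against Hardy-Weinberg genotype proportions.

    Females are diploid for chrX, so the three genotype classes
    (non-carrier, heterozygous carrier, homozygous carrier) can be tested
    against p^2 / 2pq / q^2 with q estimated from the observed carrier
    allele count.  ``df`` defaults to 2 (chi-square over the three classes
    without subtracting the estimated parameter); pass ``df=1`` for the
    textbook correction.
    """
    if n_females <= 0:
        raise ValueError("n_females must be positive")
    if n_het < 0 or n_hom_carrier < 0 or n_het + n_hom_carrier > n_females:
        raise ValueError("genotype counts inconsistent with n_females")
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    q = (n_het + 2 * n_hom_carrier) / (2 * n_females)
    p = 1.0 - q
    expected = (n_females * p * p, n_females * 2 * p * q, n_females * q * q)
    observed = (n_females - n_het - n_hom_carrier, n_het, n_hom_carrier)
    chi2 = 0.0
    for obs, exp in zip(observed, expected):
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
        elif obs > 0:
            chi2 = float("inf")
    p_value = float(sps.chi2.sf(chi2, df)) if math.isfinite(chi2) else 0.0
    return HWEResult(
        n_females=n_females,
        n_het=n_het,
        n_hom_carrier=n_hom_carrier,
        allele_freq=q,
        chi2=chi2,
        df=df,
        p_value=p_value,
        expected=expected,
    )


def hwe_from_genotypes(
    genotypes: Iterable[RepeatGenotype],
    catalog: LocusCatalog | None = None,
    df: int = 2,
) -> HWEResult:
    """HWE test from female genotypes, counting expanded-allele carriers."""
    if catalog is None:
        catalog = default_catalog()
    prem = RangeClass.PREMUTATION
    n_f = n_het = n_hom = 0
    for g in genotypes:
        if g.sex.value != "female" or g.is_no_call:
            continue
        n_f += 1
        n_carrier_alleles = sum(
            1 for n in g.lengths if classify_allele(n, catalog) >= prem
        )
        if n_carrier_alleles == 1:
            n_het += 1
        elif n_carrier_alleles == 2:
            n_hom += 1
    return hwe_female_chi2(n_het, n_hom, n_f, df=df)


# ---------------------------------------------------------------------------
# Parental-age Z-test
# ---------------------------------------------------------------------------

def parental_age_ztest(
    ages_group1: Sequence[float], ages_group2: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Z-test on mean ages; returns (z, two-sided p)."""
    x = np.asarray(ages_group1, dtype=float)
    y = np.asarray(ages_group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    se = math.sqrt(x.var(ddof=1) / x.size + y.var(ddof=1) / y.size)
    if se == 0:
        z = 0.0
    else:
        z = (x.mean() - y.mean()) / se
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return z, min(p, 1.0)


# ---------------------------------------------------------------------------
# Prevalence summary
# ---------------------------------------------------------------------------

#: Report row order: the six family roles, pooled offspring rows, total.
PREVALENCE_ROWS = (
    "father",
    "mother",
    "male_proband",
    "male_sibling",
    "female_proband",
    "female_sibling",
    "male_offspring",
    "female_offspring",
    "total",
)

_POOLED = {
    "male_offspring": ("male_proband", "male_sibling"),
    "female_offspring": ("female_proband", "female_sibling"),
}


@dataclass(frozen=True)
class PrevalenceRow:
    processed: int
    genotyped: int
    carriers: int

    def __post_init__(self) -> None:
        if not (0 <= self.carriers <= self.genotyped <= self.processed):
            raise ValueError(
                f"need carriers <= genotyped <= processed, got "
                f"{self.carriers}/{self.genotyped}/{self.processed}"
            )

    @property
    def noncarriers(self) -> int:
        return self.genotyped - self.carriers

    @property
    def percent(self) -> float | None:
        """Carrier percentage of genotyped samples; None if none genotyped."""
        if self.genotyped == 0:
            return None
        return 100.0 * self.carriers / self.genotyped


@dataclass
class PrevalenceSummary:
    cohort_id: str
    rows: dict[str, PrevalenceRow]

    @classmethod
    def from_role_counts(
        cls, role_rows: Mapping[str, PrevalenceRow], cohort_id: str = "cohort"
    ) -> "PrevalenceSummary":
        """Build the full summary (pooled + total rows) from per-role rows."""
        rows = dict(role_rows)
        base = [r for r in PREVALENCE_ROWS[:6] if r in rows]
        for pooled, parts in _POOLED.items():
            members = [rows[p] for p in parts if p in rows]
            if members:
                rows[pooled] = PrevalenceRow(
                    processed=sum(m.processed for m in members),
                    genotyped=sum(m.genotyped for m in members),
                    carriers=sum(m.carriers for m in members),
                )
        members = [rows[r] for r in base]
        rows["total"] = PrevalenceRow(
            processed=sum(m.processed for m in members),
            genotyped=sum(m.genotyped for m in members),
            carriers=sum(m.carriers for m in members),
        )
        return cls(cohort_id=cohort_id, rows=rows)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for key in PREVALENCE_ROWS:
            if key not in self.rows:
                continue
            r = self.rows[key]
            recs.append(
                {
                    "group": key,
                    "processed": r.processed,
                    "genotyped": r.genotyped,
                    "carriers": r.carriers,
                    "noncarriers": r.noncarriers,
                    "percent": None if r.percent is None else round(r.percent, 2),
                }
            )
        return pd.DataFrame(recs)


def summarize_prevalence(
    genotypes: Mapping[str, RepeatGenotype],
    roles: Mapping[str, FamilyRole],
    catalog: LocusCatalog | None = None,
    cohort_id: str = "cohort",
) -> PrevalenceSummary:
    """Per-role carrier prevalence from genotypes joined to pedigree roles.

    ``processed`` counts every sample with a genotype record for the role
    (no-calls included); ``genotyped`` and the percentage denominator
    exclude no-calls.
    """
    if catalog is None:
        catalog = default_catalog()
    acc: dict[str, list[int]] = {r: [0, 0, 0] for r in PREVALENCE_ROWS[:6]}
    for sid, role in roles.items():
        gt = genotypes.get(sid)
        if gt is None:
            continue
        cell = acc[role.value]
        cell[0] += 1
        if gt.is_no_call:
            continue
        cell[1] += 1
        status = classify_individual(gt, catalog)
        if status.is_expanded:
            cell[2] += 1
    role_rows = {
        name: PrevalenceRow(processed=v[0], genotyped=v[1], carriers=v[2])
        for name, v in acc.items()
    }
    return PrevalenceSummary.from_role_counts(role_rows, cohort_id=cohort_id)


# ---------------------------------------------------------------------------
# Call-set concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceRecord:
    sample_id: str
    genotype_a: str
    genotype_b: str
    class_a: RangeClass
    class_b: RangeClass

    @property
    def class_concordant(self) -> bool:
        return self.class_a is self.class_b


@dataclass
class ConcordanceSummary:
    """Longest-allele range-class agreement between two call sets."""

    records: list[ConcordanceRecord] = field(default_factory=list)

    @property
    def n_flagged_a(self) -> int:
        """Samples the first call set flags as expanded (>= premutation)."""
        return sum(1 for r in self.records if r.class_a >= RangeClass.PREMUTATION)

    @property
    def n_flagged_b(self) -> int:
        return sum(1 for r in self.records if r.class_b >= RangeClass.PREMUTATION)

    @property
    def n_class_discordant(self) -> int:
        return sum(1 for r in self.records if not r.class_concordant)

    def flagged_a_records(self) -> list[ConcordanceRecord]:
        return [r for r in self.records if r.class_a >= RangeClass.PREMUTATION]

    def count_b_class_among_flagged_a(self, range_class: RangeClass) -> int:
        """Among samples flagged by call set A, how many have that class in B."""
        return sum(1 for r in self.flagged_a_records() if r.class_b is range_class)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "genotype_a": r.genotype_a,
                    "genotype_b": r.genotype_b,
                    "class_a": r.class_a.value,
                    "class_b": r.class_b.value,
                    "concordant": r.class_concordant,
                }
                for r in self.records
            ]
        )


def callset_concordance(
    calls_a: Iterable[RepeatGenotype],
    calls_b: Iterable[RepeatGenotype],
    catalog: LocusCatalog | None = None,
) -> ConcordanceSummary:
    """Compare two call sets sample-by-sample on longest-allele class.

    Samples present in only one set (or no-called in either) are excluded
    with a warning.
    """
    if catalog is None:
        catalog = default_catalog()
    a_by_id = {g.sample_id: g for g in calls_a}
    b_by_id = {g.sample_id: g for g in calls_b}
    only = set(a_by_id) ^ set(b_by_id)
    if only:
        logger.warning(
            "%d sample(s) present in only one call set; excluded: %s",
            len(only),
            ", ".join(sorted(only)[:5]),
        )
    summary = ConcordanceSummary()
    for sid in sorted(set(a_by_id) & set(b_by_id)):
        ga, gb = a_by_id[sid], b_by_id[sid]
        if ga.is_no_call or gb.is_no_call:
            logger.warning("%s: no-call in one mode; excluded", sid)
            continue
        sa = classify_individual(ga, catalog)
        sb = classify_individual(gb, catalog)
        summary.records.append(
            ConcordanceRecord(
                sample_id=sid,
                genotype_a=ga.genotype_string(),
                genotype_b=gb.genotype_string(),
                class_a=sa.longest_class,
                class_b=sb.longest_class,
            )
        )
    return summary
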