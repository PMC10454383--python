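"""X-linked parental-origin assignment and transmission categorization.

For an X-linked locus, a son's single allele must come from his mother
and a daughter carries one paternal and one maternal X.  Measured repeat
lengths drift between generations (both true germline instability and
genotyping scatter), so origin assignment is by minimum absolute length
difference: a son's allele is matched to the nearest maternal allele, and
a daughter's two alleles are partitioned one-paternal/one-maternal by the
assignment minimizing the total absolute difference.  Matches whose
length discrepancy exceeds a tolerance are flagged, never dropped.

Each offspring allele then falls into one of four categories:

* ``premutation_transmitted`` — an expanded (premutation-or-longer) allele
  matched to a parental allele that is itself expanded;
* ``de_novo`` — an expanded offspring allele whose assigned parental
  allele is below the premutation range;
* ``normal_from_carrier`` — a below-premutation offspring allele whose
  transmitting parent carries a premutation-range allele (the offspring
  did not inherit the expansion);
* ``normal`` — the unremarkable case, not tabulated in reports.

A son whose expanded allele is only explainable by his father's
premutation allele is an X-linkage violation: flagged and reported but
never counted as a transmission.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import LocusCatalog, RangeClass, classify_allele, default_catalog
from .io import Family, FamilyRole, RepeatGenotype, Sex

logger = logging.getLogger(__name__)

#: Matches with |offspring - parent| above this many repeat units get a
#: ``poor_match`` flag (genotyping scatter of a few units is routine).
DEFAULT_MATCH_TOLERANCE = 5


class Origin(enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    DE_NOVO = "de_novo"


class QCFlag(enum.Enum):
    X_LINKAGE_VIOLATION = "x_linkage_violation"
    AMBIGUOUS_MATCH = "ambiguous_match"
    POOR_MATCH = "poor_match"
    CONTRACTION = "contraction"


class TransmissionCategory(enum.Enum):
    PREMUTATION_TRANSMITTED = "premutation_transmitted"
    NORMAL_FROM_CARRIER = "normal_from_carrier"
    DE_NOVO = "de_novo"
    NORMAL = "normal"


@dataclass(frozen=True)
class AlleleAssignment:
    """One offspring allele matched to a parental origin."""

    offspring_allele: int
    origin: Origin  # maternal or paternal (never de_novo at this stage)
    parent_allele: int
    delta: int
    flags: frozenset[QCFlag] = frozenset()


@dataclass(frozen=True)
class TransmissionCall:
    family_id: str
    offspring_id: str
    offspring_role: FamilyRole
    origin: Origin
    offspring_allele: int
    assigned_parent_allele: int | None
    transmitted_class: RangeClass
    parent_class: RangeClass | None
    category: TransmissionCategory
    delta: int
    qc_flags: frozenset[QCFlag] = frozenset()


def _nearest(allele: int, candidates: Sequence[int]) -> tuple[int, int, bool]:
    """Return (matched candidate, signed delta, tie?) for the nearest match.

    Ties break toward the smaller candidate allele (deterministic).
    """
    best = min(candidates, key=lambda c: (abs(allele - c), c))
    tie = len({c for c in candidates if abs(allele - c) == abs(allele - best)}) > 1
    return best, allele - best, tie


def assign_parental_origin(
    offspring: RepeatGenotype,
    father: RepeatGenotype,
    mother: RepeatGenotype,
    tolerance: int = DEFAULT_MATCH_TOLERANCE,
) -> list[AlleleAssignment]:
    """Assign each offspring allele a parental origin by length matching.

    Sons: the single allele goes to the nearest maternal allele (a son's X
    is always maternal).  Daughters: both (paternal-allele, maternal-allele)
    partitions are scored by total absolute difference and the cheaper one
    wins; the maternal slot matches the nearer of the mother's two alleles.
    """
    if father.sex is not Sex.MALE or mother.sex is not Sex.FEMALE:
        raise ValueError("parental genotypes have inconsistent sexes")
    if offspring.is_no_call or father.is_no_call or mother.is_no_call:
        raise ValueError("origin assignment requires called genotypes")

    maternal = mother.lengths
    paternal = father.lengths[0]

    def _flags(delta: int, tie: bool) -> frozenset[QCFlag]:
        flags = set()
        if abs(delta) > tolerance:
            flags.add(QCFlag.POOR_MATCH)
        if tie:
            flags.add(QCFlag.AMBIGUOUS_MATCH)
        return frozenset(flags)

    if offspring.sex is Sex.MALE:
        allele = offspring.lengths[0]
        matched, delta, tie = _nearest(allele, maternal)
        return [
            AlleleAssignment(allele, Origin.MATERNAL, matched, delta, _flags(delta, tie))
        ]

    a0, a1 = offspring.lengths
    partitions = []
    for pat, mat in ((a0, a1), (a1, a0)):
        m_match, m_delta, m_tie = _nearest(mat, maternal)
        cost = abs(pat - paternal) + abs(m_delta)
        partitions.append((cost, pat, mat, m_match, m_delta, m_tie))
    partitions.sort(key=lambda t: t[0])
    ambiguous = a0 != a1 and partitions[0][0] == partitions[1][0]
    cost, pat, mat, m_match, m_delta, m_tie = partitions[0]
    pat_delta = pat - paternal
    pat_flags = set(_flags(pat_delta, False))
    mat_flags = set(_flags(m_delta, m_tie))
    if ambiguous:
        pat_flags.add(QCFlag.AMBIGUOUS_MATCH)
        mat_flags.add(QCFlag.AMBIGUOUS_MATCH)
    out = [
        AlleleAssignment(pat, Origin.PATERNAL, paternal, pat_delta, frozenset(pat_flags)),
        AlleleAssignment(mat, Origin.MATERNAL, m_match, m_delta, frozenset(mat_flags)),
    ]
    out.sort(key=lambda a: a.offspring_allele)
    return out


def classify_transmissions(
    family: Family,
    genotypes: Mapping[str, RepeatGenotype],
    catalog: LocusCatalog | None = None,
    tolerance: int = DEFAULT_MATCH_TOLERANCE,
) -> list[TransmissionCall]:
    """Categorize every offspring allele in one analysis-ready family.

    Families lacking a called genotype for either parent are skipped with
    a warning (de novo claims need both parents excluded as the source).
    """
    if catalog is None:
        catalog = default_catalog()
    if not family.analysis_ready:
        logger.warning("family %s is not analysis-ready; skipped", family.family_id)
        return []
    father_gt = genotypes.get(family.father.sample_id)
    mother_gt = genotypes.get(family.mother.sample_id)
    if (
        father_gt is None
        or mother_gt is None
        or father_gt.is_no_call
        or mother_gt.is_no_call
    ):
        logger.warning(
            "family %s: missing parental genotype; skipped", family.family_id
        )
        return []

    prem = RangeClass.PREMUTATION
    father_classes = [classify_allele(n, catalog) for n in father_gt.lengths]
    mother_classes = [classify_allele(n, catalog) for n in mother_gt.lengths]
    father_carrier = any(c >= prem for c in father_classes)
    mother_carrier = any(c >= prem for c in mother_classes)

    calls: list[TransmissionCall] = []
    for child in family.offspring:
        role = family.role(child.sample_id)
        child_gt = genotypes.get(child.sample_id)
        if role is None or child_gt is None or child_gt.is_no_call:
            continue
        assignments = assign_parental_origin(child_gt, father_gt, mother_gt, tolerance)
        for asg in assignments:
            child_class = classify_allele(asg.offspring_allele, catalog)
            parent_class = classify_allele(asg.parent_allele, catalog)
            parent_is_mother = asg.origin is Origin.MATERNAL
            parent_carrier = mother_carrier if parent_is_mother else father_carrier
            flags = set(asg.flags)
            origin = asg.origin
            if child_class >= prem:
                if parent_class >= prem:
                    category = TransmissionCategory.PREMUTATION_TRANSMITTED
                else:
                    category = TransmissionCategory.DE_NOVO
                    origin = Origin.DE_NOVO
                    # an expanded son matching only the father's expanded
                    # allele cannot be a real transmission on chrX
                    if (
                        child_gt.sex is Sex.MALE
                        and father_carrier
                        and not mother_carrier
                        and abs(asg.offspring_allele - father_gt.lengths[0]) <= tolerance
                        and abs(asg.delta) > tolerance
                    ):
                        flags.add(QCFlag.X_LINKAGE_VIOLATION)
            else:
                if parent_class >= prem:
                    # matched to a parental premutation allele but measured
                    # below the premutation range: apparent contraction
                    flags.add(QCFlag.CONTRACTION)
                    category = TransmissionCategory.NORMAL_FROM_CARRIER
                elif parent_carrier:
                    category = TransmissionCategory.NORMAL_FROM_CARRIER
                else:
                    category = TransmissionCategory.NORMAL
            calls.append(
                TransmissionCall(
                    family_id=family.family_id,
                    offspring_id=child.sample_id,
                    offspring_role=role,
                    origin=origin,
                    offspring_allele=asg.offspring_allele,
                    assigned_parent_allele=asg.parent_allele,
                    transmitted_class=child_class,
                    parent_class=parent_class,
                    category=category,
                    delta=asg.delta,
                    qc_flags=frozenset(flags),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Summary (the 16 transmission rows + 4 de novo rows)
# ---------------------------------------------------------------------------

_OFFSPRING_ROLES = (
    FamilyRole.MALE_PROBAND,
    FamilyRole.MALE_SIBLING,
    FamilyRole.FEMALE_PROBAND,
    FamilyRole.FEMALE_SIBLING,
)

#: (parent, offspring role, transmitted range) keys, in report row order.
TRANSMISSION_ROWS: tuple[tuple[str, FamilyRole, str], ...] = tuple(
    (parent, role, rng)
    for rng in ("premutation", "normal")
    for parent in ("mother", "father")
    for role in _OFFSPRING_ROLES
)


@dataclass
class TransmissionSummary:
    """Cohort-level transmission accounting.

    ``counts`` holds the 16 (parent, role, range) transmission rows;
    ``de_novo_counts`` the 4 per-role de novo rows.  Percentages use the
    number of genotyped offspring in premutation-carrier families as the
    denominator.
    """

    cohort_id: str
    counts: dict[tuple[str, FamilyRole, str], int]
    de_novo_counts: dict[FamilyRole, int]
    n_offspring_in_carrier_families: int
    n_carrier_families: int
    n_x_violations: int = 0

    def __post_init__(self) -> None:
        for role in (FamilyRole.MALE_PROBAND, FamilyRole.MALE_SIBLING):
            for rng in ("premutation", "normal"):
                assert self.counts.get(("father", role, rng), 0) == 0, (
                    "father-to-male transmission is impossible for an "
                    "X-linked locus"
                )

    @property
    def n_premutation_transmitted(self) -> int:
        return sum(
            v for (_, _, rng), v in self.counts.items() if rng == "premutation"
        )

    @property
    def n_noninheriting(self) -> int:
        return sum(v for (_, _, rng), v in self.counts.items() if rng == "normal")

    @property
    def n_de_novo(self) -> int:
        return sum(self.de_novo_counts.values())

    def percentage(self, count: int) -> float:
        """Percentage of offspring in carrier families; 0.0 if empty cohort."""
        if self.n_offspring_in_carrier_families == 0:
            if count:
                logger.warning("nonzero count with zero denominator")
            return 0.0
        return 100.0 * count / self.n_offspring_in_carrier_families

    def to_frame(self) -> pd.DataFrame:
        """Report table in the conventional 20-row order."""
        rows = []
        label = {
            FamilyRole.MALE_PROBAND: "Male Proband",
            FamilyRole.MALE_SIBLING: "Male Sibling",
            FamilyRole.FEMALE_PROBAND: "Female Proband",
            FamilyRole.FEMALE_SIBLING: "Female Sibling",
        }
        for parent, role, rng in TRANSMISSION_ROWS:
            count = self.counts.get((parent, role, rng), 0)
            rows.append(
                {
                    "transmission": f"{parent.capitalize()} to {label[role]}",
                    "allele": f"{rng.capitalize()} Range Allele",
                    "count": count,
                    "percent": round(self.percentage(count), 2),
                }
            )
        for role in _OFFSPRING_ROLES:
            count = self.de_novo_counts.get(role, 0)
            rows.append(
                {
                    "transmission": label[role],
                    "allele": "de novo",
                    "count": count,
                    "percent": round(self.percentage(count), 2),
                }
            )
        return pd.DataFrame(rows)


def carrier_families(
    families: Mapping[str, Family],
    genotypes: Mapping[str, RepeatGenotype],
    catalog: LocusCatalog | None = None,
) -> set[str]:
    """Family ids with at least one member carrying an expanded allele."""
    if catalog is None:
        catalog = default_catalog()
    prem = RangeClass.PREMUTATION
    out = set()
    for fam_id, fam in families.items():
        for sid in fam.members:
            gt = genotypes.get(sid)
            if gt is None or gt.is_no_call:
                continue
            if any(classify_allele(n, catalog) >= prem for n in gt.lengths):
                out.add(fam_id)
                break
    return out


def summarize_transmissions(
    calls: Iterable[TransmissionCall],
    families: Mapping[str, Family],
    genotypes: Mapping[str, RepeatGenotype],
    catalog: LocusCatalog | None = None,
    cohort_id: str = "cohort",
) -> TransmissionSummary:
    """Tabulate transmission calls over premutation-carrier families."""
    if catalog is None:
        catalog = default_catalog()
    carrier_ids = carrier_families(families, genotypes, catalog)
    n_offspring = 0
    for fam_id in carrier_ids:
        for child in families[fam_id].offspring:
            gt = genotypes.get(child.sample_id)
            if gt is not None and not gt.is_no_call:
                n_offspring += 1

    counts: dict[tuple[str, FamilyRole, str], int] = {k: 0 for k in TRANSMISSION_ROWS}
    de_novo: dict[FamilyRole, int] = {r: 0 for r in _OFFSPRING_ROLES}
    n_viol = 0
    for call in calls:
        if call.family_id not in carrier_ids:
            continue
        if QCFlag.X_LINKAGE_VIOLATION in call.qc_flags:
            n_viol += 1
            continue
        if call.category is TransmissionCategory.DE_NOVO:
            de_novo[call.offspring_role] += 1
        elif call.category is TransmissionCategory.PREMUTATION_TRANSMITTED:
            parent = "mother" if call.origin is Origin.MATERNAL else "father"
            counts[(parent, call.offspring_role, "premutation")] += 1
        elif call.category is TransmissionCategory.NORMAL_FROM_CARRIER:
            parent = "mother" if call.origin is Origin.MATERNAL else "father"
            counts[(parent, call.offspring_role, "normal")] += 1
    return TransmissionSummary(
        cohort_id=cohort_id,
        counts=counts,
        de_novo_counts=de_novo,
        n_offspring_in_carrier_families=n_offspring,
        n_carrier_families=len(carrier_ids),
        n_x_violations=n_viol,
    )


def calls_to_frame(calls: Iterable[TransmissionCall]) -> pd.DataFrame:
    """Per-call audit table (deltas and QC flags) for TSV export."""
    rows = []
    for c in calls:
        rows.append(
            {
                "family_id": c.family_id,
                "offspring_id": c.offspring_id,
                "role": c.offspring_role.value,
                "origin": c.origin.value,
                "offspring_allele": c.offspring_allele,
                "parent_allele": c.assigned_parent_allele,
                "transmitted_class": c.transmitted_class.value,
                "parent_class": c.parent_class.value if c.parent_class else "",
                "category": c.category.value,
                "delta": c.delta,
                "qc_flags": ",".join(sorted(f.value for f in c.qc_flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "offspring_id",
            "role",
            "origin",
            "offspring_allele",
            "parent_allele",
            "transmitted_class",
            "parent_class",
            "category",
            "delta",
            "qc_flags",
        ],
    )
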