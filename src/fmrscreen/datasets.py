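"""Published FMR1 screening summary data used for validation and examples.

These are the printed results of a large-scale WGS-based FMR1 CGG
carrier screen of the SSC and SPARK ASD family cohorts: the 16-sample
PCR-validation genotype table (four quad families genotyped by PCR and
by ExpansionHunter with and without off-target reads), the per-role
carrier-count tables for both cohorts, and the per-category transmission
counts.  The underlying individual-level WGS data are access-restricted;
these summary counts are the public record against which this package's
statistics can be recomputed and checked.

Only raw counts and genotypes are stored here — every derived quantity
(odds ratio, chi-square, percentage, concordance count) is computed at
run time by the package's own operations.
"""

from __future__ import annotations

from .io import CallMode, RepeatGenotype, Sex, parse_pcr_genotype
from .stats import PrevalenceRow

# ---------------------------------------------------------------------------
# PCR validation table: four SSC quad families, three call modes per sample.
# Columns: sample, family, role, PCR, EH with off-target reads, EH region-only.
# ---------------------------------------------------------------------------

VALIDATION_TABLE: tuple[tuple[str, str, str, str, str, str], ...] = (
    ("SSC02135", "11372", "father", "Y/23", "Y/23", "Y/23"),
    ("SSC02130", "11372", "mother", "29/48", "29/70", "29/70"),
    ("SSC02128", "11372", "male_proband", "Y/48", "Y/46", "Y/46"),
    ("SSC02136", "11372", "male_sibling", "Y/48", "Y/57", "Y/51"),
    ("SSC02349", "11676", "father", "Y/27", "Y/281", "Y/27"),
    ("SSC02338", "11676", "mother", "29/30", "29/30", "29/30"),
    ("SSC02330", "11676", "female_proband", "27/30", "27/30", "27/30"),
    ("SSC02350", "11676", "female_sibling", "27/29", "27/29", "27/29"),
    ("SSC07297", "13390", "father", "Y/30", "Y/30", "Y/30"),
    ("SSC07289", "13390", "mother", "30/33", "30/33", "30/33"),
    ("SSC07282", "13390", "male_proband", "Y/33", "Y/157", "Y/71"),
    ("SSC07298", "13390", "female_sibling", "30/30", "30/30", "30/30"),
    ("SSC12025", "14489", "father", "Y/30", "Y/30", "Y/30"),
    ("SSC12020", "14489", "mother", "39/46", "39/92", "38/68"),
    ("SSC12016", "14489", "male_proband", "Y/39", "Y/128", "Y/71"),
    ("SSC12026", "14489", "male_sibling", "Y/39", "Y/168", "Y/72"),
)

_MODE_COLUMN = {
    CallMode.PCR: 3,
    CallMode.EH_OFFTARGET: 4,
    CallMode.EH_REGION_ONLY: 5,
}


def validation_genotypes(mode: CallMode) -> list[RepeatGenotype]:
    """The 16 PCR-validation samples under one call mode."""
    col = _MODE_COLUMN[mode]
    out = []
    for row in VALIDATION_TABLE:
        gt = row[col]
        sex = Sex.MALE if gt.startswith("Y/") else Sex.FEMALE
        g = parse_pcr_genotype(row[0], sex, gt)
        out.append(
            RepeatGenotype(g.sample_id, g.locus_id, g.sex, g.alleles, mode)
        )
    return out


# ---------------------------------------------------------------------------
# Per-role carrier counts (processed, genotyped, premutation carriers).
# ---------------------------------------------------------------------------

SSC_ROLE_COUNTS: dict[str, PrevalenceRow] = {
    "father": PrevalenceRow(2364, 2362, 22),
    "mother": PrevalenceRow(2369, 2365, 42),
    "male_proband": PrevalenceRow(2060, 2055, 13),
    "male_sibling": PrevalenceRow(906, 905, 8),
    "female_proband": PrevalenceRow(321, 321, 6),
    "female_sibling": PrevalenceRow(1011, 1008, 11),
}

SPARK_ROLE_COUNTS: dict[str, PrevalenceRow] = {
    "father": PrevalenceRow(3075, 3067, 19),
    "mother": PrevalenceRow(3078, 3077, 22),
    "male_proband": PrevalenceRow(2509, 2497, 16),
    "male_sibling": PrevalenceRow(1133, 1127, 4),
    "female_proband": PrevalenceRow(614, 614, 7),
    "female_sibling": PrevalenceRow(1136, 1136, 10),
}

# ---------------------------------------------------------------------------
# Transmission counts per category, and the carrier-family offspring
# denominators (SSC: 141 offspring in 79 carrier families; SPARK: 99 in 58).
# Keys: (parent, offspring role, transmitted range) or role for de novo.
# ---------------------------------------------------------------------------

SSC_TRANSMISSION_COUNTS: dict[tuple[str, str, str], int] = {
    ("mother", "male_proband", "premutation"): 10,
    ("mother", "male_sibling", "premutation"): 7,
    ("mother", "female_proband", "premutation"): 3,
    ("mother", "female_sibling", "premutation"): 6,
    ("father", "male_proband", "premutation"): 0,
    ("father", "male_sibling", "premutation"): 0,
    ("father", "female_proband", "premutation"): 2,
    ("father", "female_sibling", "premutation"): 4,
    ("mother", "male_proband", "normal"): 19,
    ("mother", "male_sibling", "normal"): 14,
    ("mother", "female_proband", "normal"): 2,
    ("mother", "female_sibling", "normal"): 7,
    ("father", "male_proband", "normal"): 0,
    ("father", "male_sibling", "normal"): 0,
    ("father", "female_proband", "normal"): 0,
    ("father", "female_sibling", "normal"): 0,
}
SSC_DE_NOVO_COUNTS: dict[str, int] = {
    "male_proband": 3,
    "male_sibling": 1,
    "female_proband": 0,
    "female_sibling": 1,
}
SSC_N_OFFSPRING_IN_CARRIER_FAMILIES = 141
SSC_N_CARRIER_FAMILIES = 79

SPARK_TRANSMISSION_COUNTS: dict[tuple[str, str, str], int] = {
    ("mother", "male_proband", "premutation"): 15,
    ("mother", "male_sibling", "premutation"): 4,
    ("mother", "female_proband", "premutation"): 3,
    ("mother", "female_sibling", "premutation"): 4,
    ("father", "male_proband", "premutation"): 0,
    ("father", "male_sibling", "premutation"): 0,
    ("father", "female_proband", "premutation"): 3,
    ("father", "female_sibling", "premutation"): 5,
    ("mother", "male_proband", "normal"): 11,
    ("mother", "male_sibling", "normal"): 6,
    ("mother", "female_proband", "normal"): 2,
    ("mother", "female_sibling", "normal"): 7,
    ("father", "male_proband", "normal"): 0,
    ("father", "male_sibling", "normal"): 0,
    ("father", "female_proband", "normal"): 0,
    ("father", "female_sibling", "normal"): 0,
}
SPARK_DE_NOVO_COUNTS: dict[str, int] = {
    "male_proband": 1,
    "male_sibling": 0,
    "female_proband": 1,
    "female_sibling": 1,
}
SPARK_N_OFFSPRING_IN_CARRIER_FAMILIES = 99
SPARK_N_CARRIER_FAMILIES = 58


def transmission_summary(cohort: str) -> "TransmissionSummary":
    """Published transmission counts as a :class:`TransmissionSummary`.

    ``cohort`` is ``"ssc"`` or ``"spark"``; percentages and aggregates are
    then computed by the summary object itself.
    """
    from .io import FamilyRole
    from .transmission import TransmissionSummary

    if cohort == "ssc":
        counts, de_novo = SSC_TRANSMISSION_COUNTS, SSC_DE_NOVO_COUNTS
        n_off, n_fam = SSC_N_OFFSPRING_IN_CARRIER_FAMILIES, SSC_N_CARRIER_FAMILIES
    elif cohort == "spark":
        counts, de_novo = SPARK_TRANSMISSION_COUNTS, SPARK_DE_NOVO_COUNTS
        n_off, n_fam = SPARK_N_OFFSPRING_IN_CARRIER_FAMILIES, SPARK_N_CARRIER_FAMILIES
    else:
        raise ValueError(f"unknown cohort {cohort!r}")
    return TransmissionSummary(
        cohort_id=cohort,
        counts={
            (parent, FamilyRole(role), rng): v
            for (parent, role, rng), v in counts.items()
        },
        de_novo_counts={FamilyRole(r): v for r, v in de_novo.items()},
        n_offspring_in_carrier_families=n_off,
        n_carrier_families=n_fam,
    )
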