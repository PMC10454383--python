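"""Reading and writing repeat genotypes and pedigrees.

Supported genotype sources:

* ExpansionHunter-style JSON (one file per sample, ``LocusResults`` with
  ``Genotype``/``GenotypeConfidenceInterval`` strings),
* VCF with per-sample ``REPCN`` (repeat count) and ``REPCI`` (confidence
  interval) FORMAT fields, read through :mod:`pysam`,
* PCR result tables (TSV with ``Y/a`` male notation), and
* the package's own normalized TSV genotype table (round-trip safe).

Pedigrees are 6-column PED.  All readers enforce sex-aware ploidy for
X-linked loci at parse time: one allele for males, two for females.
A sample the genotyper skipped (e.g. below-coverage) is an explicit
no-call record with an empty allele list, never a silent omission.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .catalog import ChromosomeType, LocusCatalog, default_catalog

logger = logging.getLogger(__name__)

# FMR1 CGG repeat reference region (hg38), used when emitting VCF.
FMR1_CHROM = "chrX"
FMR1_POS = 147912050
FMR1_END = 147912110


class FormatError(ValueError):
    """Malformed genotype or pedigree input."""


class PloidyError(FormatError):
    """Allele count inconsistent with declared sex for an X-linked locus."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Affected(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class CallMode(enum.Enum):
    """Provenance of a repeat call.

    ``eh_offtarget``: genotyper run with off-target regions enabled (prone
    to inflating long alleles); ``eh_region_only``: restricted to the locus
    reference region; ``pcr``: repeat-primed PCR sizing.
    """

    EH_OFFTARGET = "eh_offtarget"
    EH_REGION_ONLY = "eh_region_only"
    PCR = "pcr"


class FamilyRole(enum.Enum):
    FATHER = "father"
    MOTHER = "mother"
    MALE_PROBAND = "male_proband"
    FEMALE_PROBAND = "female_proband"
    MALE_SIBLING = "male_sibling"
    FEMALE_SIBLING = "female_sibling"

    @property
    def is_offspring(self) -> bool:
        return self not in (FamilyRole.FATHER, FamilyRole.MOTHER)


@dataclass(frozen=True)
class RepeatAllele:
    repeat_units: int
    ci_low: int | None = None
    ci_high: int | None = None

    def __post_init__(self) -> None:
        if self.repeat_units < 0:
            raise FormatError(f"negative repeat count: {self.repeat_units}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise FormatError("confidence interval must have both bounds or neither")
        if self.ci_low is not None:
            if not (self.ci_low <= self.repeat_units <= self.ci_high):
                raise FormatError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not cover "
                    f"allele of {self.repeat_units} repeat units"
                )


@dataclass(frozen=True)
class RepeatGenotype:
    """A sex-aware repeat genotype at one locus.

    ``alleles`` is sorted ascending by repeat count.  An empty allele list
    marks a no-call (sample processed but not genotyped).
    """

    sample_id: str
    locus_id: str
    sex: Sex
    alleles: tuple[RepeatAllele, ...]
    call_mode: CallMode = CallMode.EH_OFFTARGET

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "alleles",
            tuple(sorted(self.alleles, key=lambda a: a.repeat_units)),
        )

    @property
    def is_no_call(self) -> bool:
        return len(self.alleles) == 0

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(a.repeat_units for a in self.alleles)

    def validate_ploidy(self, catalog: LocusCatalog | None = None) -> None:
        if catalog is None:
            catalog = default_catalog()
        if self.is_no_call:
            return
        if catalog.chromosome_type is ChromosomeType.CHR_X:
            expected = 1 if self.sex is Sex.MALE else 2
            if len(self.alleles) != expected:
                raise PloidyError(
                    f"{self.sample_id}: {self.sex.value} sample has "
                    f"{len(self.alleles)} allele(s) at X-linked locus "
                    f"{self.locus_id}, expected {expected}"
                )

    def genotype_string(self) -> str:
        """Render in the screening convention: ``Y/23`` for males, ``a/b``
        for females, ``.`` for a no-call."""
        if self.is_no_call:
            return "."
        if self.sex is Sex.MALE:
            return f"Y/{self.alleles[0].repeat_units}"
        return "/".join(str(a.repeat_units) for a in self.alleles)


# ---------------------------------------------------------------------------
# ExpansionHunter-style JSON
# ---------------------------------------------------------------------------

def _parse_ci(ci: str) -> tuple[int, int]:
    lo, _, hi = ci.partition("-")
    return int(lo), int(hi)


def _genotype_from_strings(
    sample_id: str,
    locus_id: str,
    sex: Sex,
    genotype: str,
    ci: str | None,
    call_mode: CallMode,
) -> RepeatGenotype:
    try:
        counts = [int(g) for g in genotype.split("/")]
        cis: list[tuple[int, int] | None]
        if ci:
            cis = [None if c == "." else _parse_ci(c) for c in ci.split("/")]
        else:
            cis = [None] * len(counts)
        if len(cis) != len(counts):
            raise ValueError("CI/genotype arity mismatch")
        alleles = tuple(
            RepeatAllele(n, *(c if c is not None else (None, None)))
            for n, c in zip(counts, cis)
        )
    except (ValueError, FormatError) as exc:
        raise FormatError(
            f"sample {sample_id}, locus {locus_id}: malformed genotype "
            f"{genotype!r} / CI {ci!r} ({exc})"
        ) from exc
    gt = RepeatGenotype(sample_id, locus_id, sex, alleles, call_mode)
    gt.validate_ploidy()
    return gt


def read_eh_json(
    path: str | Path, call_mode: CallMode = CallMode.EH_OFFTARGET
) -> list[RepeatGenotype]:
    """Read one ExpansionHunter-style JSON output file.

    Returns one :class:`RepeatGenotype` per repeat variant in the file's
    ``LocusResults``; a locus whose ``Genotype`` is absent becomes an
    explicit no-call record.
    """
    doc = json.loads(Path(path).read_text())
    params = doc.get("SampleParameters", {})
    sample_id = params.get("SampleId", Path(path).stem)
    sex = Sex(params.get("Sex", "female").lower())
    out: list[RepeatGenotype] = []
    for locus_id, locus in doc.get("LocusResults", {}).items():
        for variant in locus.get("Variants", {}).values():
            if variant.get("VariantType", "Repeat") != "Repeat":
                continue
            genotype = variant.get("Genotype")
            if genotype is None:
                out.append(RepeatGenotype(sample_id, locus_id, sex, (), call_mode))
                continue
            out.append(
                _genotype_from_strings(
                    sample_id,
                    locus_id,
                    sex,
                    genotype,
                    variant.get("GenotypeConfidenceInterval"),
                    call_mode,
                )
            )
    return out


def write_eh_json(
    genotypes: Sequence[RepeatGenotype], path: str | Path
) -> None:
    """Write one sample's genotypes as an ExpansionHunter-style JSON file."""
    if not genotypes:
        raise ValueError("cannot write an empty genotype list")
    sample_ids = {g.sample_id for g in genotypes}
    sexes = {g.sex for g in genotypes}
    if len(sample_ids) != 1 or len(sexes) != 1:
        raise ValueError("one JSON file holds exactly one sample")
    locus_results: dict = {}
    for g in genotypes:
        variant: dict = {
            "VariantId": g.locus_id,
            "VariantType": "Repeat",
            "RepeatUnit": "CGG",
            "ReferenceRegion": f"{FMR1_CHROM}:{FMR1_POS}-{FMR1_END}",
        }
        if not g.is_no_call:
            variant["Genotype"] = "/".join(str(a.repeat_units) for a in g.alleles)
            variant["GenotypeConfidenceInterval"] = "/".join(
                f"{a.ci_low if a.ci_low is not None else a.repeat_units}-"
                f"{a.ci_high if a.ci_high is not None else a.repeat_units}"
                for a in g.alleles
            )
        locus_results[g.locus_id] = {
            "LocusId": g.locus_id,
            "AlleleCount": len(g.alleles) or (1 if g.sex is Sex.MALE else 2),
            "Variants": {g.locus_id: variant},
        }
    doc = {
        "LocusResults": locus_results,
        "SampleParameters": {
            "SampleId": next(iter(sample_ids)),
            "Sex": next(iter(sexes)).value.capitalize(),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# VCF with REPCN/REPCI per-sample fields
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length=156040895>
##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit">
##INFO=<ID=REPID,Number=1,Type=String,Description="Repeat locus identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=REPCN,Number=1,Type=String,Description="Number of repeat units spanned by each allele">
##FORMAT=<ID=REPCI,Number=1,Type=String,Description="Confidence interval for each allele">
"""


def read_eh_vcf(
    path: str | Path, call_mode: CallMode = CallMode.EH_OFFTARGET
) -> list[RepeatGenotype]:
    """Read repeat genotypes from a VCF carrying REPCN/REPCI sample fields.

    Sample sex at an X-linked locus is carried by the call's arity: a
    single repeat count (``23``) is a hemizygous male, two counts
    (``29/70``) a female.  No-calls preserve arity as ``.`` / ``./.``.
    """
    out: list[RepeatGenotype] = []
    with pysam.VariantFile(str(path)) as vcf:
        if "REPCN" not in vcf.header.formats:
            raise FormatError(f"{path}: VCF lacks the REPCN repeat-count FORMAT field")
        for rec in vcf:
            locus_id = rec.info.get("REPID", rec.id or "FMR1")
            for name, sample in rec.samples.items():
                repcn = sample.get("REPCN")
                repci = sample.get("REPCI")
                repcn = None if repcn in (None, ".") else str(repcn)
                repci = None if repci in (None, ".") else str(repci)
                if repcn is None or set(repcn.split("/")) == {"."}:
                    # arity of the missing value encodes sex
                    n_slots = len(repcn.split("/")) if repcn else 1
                    sex = Sex.MALE if n_slots == 1 else Sex.FEMALE
                    out.append(RepeatGenotype(name, locus_id, sex, (), call_mode))
                    continue
                sex = Sex.MALE if len(repcn.split("/")) == 1 else Sex.FEMALE
                out.append(
                    _genotype_from_strings(name, locus_id, sex, repcn, repci, call_mode)
                )
    return out


def write_eh_vcf(genotypes: Sequence[RepeatGenotype], path: str | Path) -> None:
    """Write genotypes as a single-locus multi-sample uncompressed VCF."""
    by_sample: dict[str, RepeatGenotype] = {}
    locus_ids = set()
    for g in genotypes:
        if g.sample_id in by_sample:
            raise ValueError(f"duplicate sample {g.sample_id} in VCF export")
        by_sample[g.sample_id] = g
        locus_ids.add(g.locus_id)
    if len(locus_ids) > 1:
        raise ValueError("VCF export supports a single locus per file")
    locus_id = next(iter(locus_ids)) if locus_ids else "FMR1"

    lines = [_VCF_HEADER.format(chrom=FMR1_CHROM)]
    samples = list(by_sample)
    if samples:
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
        )
    else:
        # a sample-less VCF has no FORMAT column and no variant rows
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        Path(path).write_text("\n".join(lines) + "\n")
        return
    calls = []
    for name in samples:
        g = by_sample[name]
        if g.is_no_call:
            slots = 1 if g.sex is Sex.MALE else 2
            gt = "/".join(["."] * slots)
            calls.append(f"{gt}:{gt}:{gt}")
        else:
            gt = "/".join("1" for _ in g.alleles)
            repcn = "/".join(str(a.repeat_units) for a in g.alleles)
            repci = "/".join(
                f"{a.ci_low if a.ci_low is not None else a.repeat_units}-"
                f"{a.ci_high if a.ci_high is not None else a.repeat_units}"
                for a in g.alleles
            )
            calls.append(f"{gt}:{repcn}:{repci}")
    row = "\t".join(
        [
            FMR1_CHROM,
            str(FMR1_POS),
            locus_id,
            "C",
            "<STR>",
            ".",
            "PASS",
            f"RU=CGG;REPID={locus_id}",
            "GT:REPCN:REPCI",
        ]
        + calls
    )
    lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PCR result tables
# ---------------------------------------------------------------------------

def parse_pcr_genotype(
    sample_id: str, sex: Sex, genotype: str, locus_id: str = "FMR1"
) -> RepeatGenotype:
    """Parse a ``29/48`` or ``Y/39`` style PCR genotype string."""
    parts = genotype.strip().split("/")
    if parts and parts[0].upper() == "Y":
        if sex is not Sex.MALE:
            raise PloidyError(
                f"{sample_id}: 'Y' hemizygosity marker in a female record"
            )
        if len(parts) != 2 or parts[1].upper() == "Y":
            raise FormatError(f"{sample_id}: malformed male genotype {genotype!r}")
        parts = parts[1:]
    try:
        alleles = tuple(RepeatAllele(int(p)) for p in parts)
    except ValueError as exc:
        raise FormatError(f"{sample_id}: malformed genotype {genotype!r}") from exc
    gt = RepeatGenotype(sample_id, locus_id, sex, alleles, CallMode.PCR)
    gt.validate_ploidy()
    return gt


def read_pcr_table(path: str | Path, locus_id: str = "FMR1") -> list[RepeatGenotype]:
    """Read a PCR genotype TSV: sample_id, sex, genotype (``a/b`` or ``Y/a``)."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "sample_id":
            continue
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
        sample_id, sex_str, genotype = fields[0], fields[1], fields[2]
        out.append(parse_pcr_genotype(sample_id, Sex(sex_str.lower()), genotype, locus_id))
    return out


# ---------------------------------------------------------------------------
# Normalized genotype table (round-trip format)
# ---------------------------------------------------------------------------

_TABLE_HEADER = "sample_id\tlocus_id\tsex\tcall_mode\tgenotype\tci"


def write_genotype_table(
    genotypes: Sequence[RepeatGenotype], path: str | Path
) -> None:
    """Write a normalized TSV; ``read_genotype_table`` inverts it exactly."""
    lines = [_TABLE_HEADER]
    for g in genotypes:
        if g.is_no_call:
            geno, ci = ".", "."
        else:
            geno = g.genotype_string()
            if any(a.ci_low is not None for a in g.alleles):
                ci = "/".join(
                    f"{a.ci_low}-{a.ci_high}" if a.ci_low is not None else "."
                    for a in g.alleles
                )
            else:
                ci = "."
        lines.append(
            f"{g.sample_id}\t{g.locus_id}\t{g.sex.value}\t{g.call_mode.value}"
            f"\t{geno}\t{ci}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype_table(path: str | Path) -> list[RepeatGenotype]:
    out: list[RepeatGenotype] = []
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _TABLE_HEADER:
        raise FormatError(f"{path}: not a genotype table (bad header)")
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 fields")
        sample_id, locus_id, sex_str, mode_str, geno, ci = fields
        sex = Sex(sex_str)
        mode = CallMode(mode_str)
        if geno == ".":
            out.append(RepeatGenotype(sample_id, locus_id, sex, (), mode))
            continue
        if geno.startswith("Y/"):
            geno = geno[2:]
        ci_str = None if ci == "." else ci
        if ci_str is not None and set(ci_str.split("/")) == {"."}:
            ci_str = None
        out.append(
            _genotype_from_strings(sample_id, locus_id, sex, geno, ci_str, mode)
        )
    return out


# ---------------------------------------------------------------------------
# Pedigrees (6-column PED)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeIndividual:
    family_id: str
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affected: Affected

    @property
    def is_offspring(self) -> bool:
        return self.father_id is not None or self.mother_id is not None


@dataclass
class Family:
    """One nuclear family with derived roles.

    ``analysis_ready`` means both parents are present plus at least one
    offspring whose parent references resolve — the precondition for
    transmission analysis.
    """

    family_id: str
    members: dict[str, PedigreeIndividual] = field(default_factory=dict)
    issues: list[str] = field(default_factory=list)

    @property
    def offspring(self) -> list[PedigreeIndividual]:
        return [m for m in self.members.values() if m.is_offspring]

    @property
    def father(self) -> PedigreeIndividual | None:
        return self._parent(Sex.MALE)

    @property
    def mother(self) -> PedigreeIndividual | None:
        return self._parent(Sex.FEMALE)

    def _parent(self, sex: Sex) -> PedigreeIndividual | None:
        ids = set()
        for child in self.offspring:
            ids.add(child.father_id if sex is Sex.MALE else child.mother_id)
        ids.discard(None)
        if len(ids) == 1:
            return self.members.get(next(iter(ids)))
        return None

    @property
    def analysis_ready(self) -> bool:
        return (
            not self.issues
            and self.father is not None
            and self.mother is not None
            and len(self.offspring) >= 1
        )

    def role(self, sample_id: str) -> FamilyRole | None:
        ind = self.members[sample_id]
        if not ind.is_offspring:
            if self.father is not None and sample_id == self.father.sample_id:
                return FamilyRole.FATHER
            if self.mother is not None and sample_id == self.mother.sample_id:
                return FamilyRole.MOTHER
            return None
        if ind.affected is Affected.AFFECTED:
            return (
                FamilyRole.MALE_PROBAND if ind.sex is Sex.MALE else FamilyRole.FEMALE_PROBAND
            )
        if ind.affected is Affected.UNAFFECTED:
            return (
                FamilyRole.MALE_SIBLING if ind.sex is Sex.MALE else FamilyRole.FEMALE_SIBLING
            )
        return None

    def roles(self) -> dict[str, FamilyRole]:
        out = {}
        for sid in self.members:
            r = self.role(sid)
            if r is not None:
                out[sid] = r
        return out


_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PED_PHENO = {"2": Affected.AFFECTED, "1": Affected.UNAFFECTED}


def read_pedigree(path: str | Path) -> dict[str, Family]:
    """Read a 6-column PED file into families keyed by family id.

    An offspring referencing a parent absent from the family is recorded
    as a family issue (the family is excluded from transmission analysis,
    not rejected outright); a parent reference of the wrong sex raises
    :class:`FormatError`.
    """
    families: dict[str, Family] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns")
        fam_id, iid, fat, mot, sex_code, pheno = fields
        if sex_code not in _PED_SEX:
            raise FormatError(f"{path}:{lineno}: unknown sex code {sex_code!r}")
        ind = PedigreeIndividual(
            family_id=fam_id,
            sample_id=iid,
            father_id=None if fat in ("0", ".") else fat,
            mother_id=None if mot in ("0", ".") else mot,
            sex=_PED_SEX[sex_code],
            affected=_PED_PHENO.get(pheno, Affected.UNKNOWN),
        )
        fam = families.setdefault(fam_id, Family(fam_id))
        if iid in fam.members:
            raise FormatError(f"{path}:{lineno}: duplicate individual {iid}")
        fam.members[iid] = ind

    for fam in families.values():
        for child in fam.offspring:
            for pid, expected_sex, label in (
                (child.father_id, Sex.MALE, "father"),
                (child.mother_id, Sex.FEMALE, "mother"),
            ):
                if pid is None:
                    fam.issues.append(
                        f"{child.sample_id}: missing {label} reference"
                    )
                    continue
                parent = fam.members.get(pid)
                if parent is None:
                    fam.issues.append(
                        f"{child.sample_id}: {label} {pid} absent from family"
                    )
                elif parent.sex is not expected_sex:
                    raise FormatError(
                        f"family {fam.family_id}: {child.sample_id} references "
                        f"{label} {pid} of the wrong sex"
                    )
        if fam.issues:
            logger.warning(
                "family %s excluded from transmission analysis: %s",
                fam.family_id,
                "; ".join(fam.issues),
            )
    return families


def write_pedigree(families: Iterable[Family], path: str | Path) -> None:
    lines = []
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2"}
    pheno_code = {Affected.AFFECTED: "2", Affected.UNAFFECTED: "1", Affected.UNKNOWN: "0"}
    for fam in families:
        for ind in fam.members.values():
            lines.append(
                "\t".join(
                    [
                        fam.family_id,
                        ind.sample_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex_code[ind.sex],
                        pheno_code[ind.affected],
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
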