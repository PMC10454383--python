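"""End-to-end screening runs: classify -> prevalence -> HWE -> transmission
-> burden -> (optional) concordance, with a run manifest and TSV/JSON
report bundle.

When two call modes are supplied (a primary, off-target-style call set
and a confirmatory region-only set), samples flagged as expanded by the
primary set are re-evaluated under the confirmatory set before final
classification — the confirmatory pass can downgrade or confirm a flag,
never add new carriers.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from . import __version__
from .catalog import LocusCatalog, RangeClass, classify_individual, default_catalog
from .io import Family, FamilyRole, RepeatGenotype, write_genotype_table
from .stats import (
    BurdenResult,
    ConcordanceSummary,
    HWEResult,
    PrevalenceSummary,
    burden_from_counts,
    callset_concordance,
    hwe_from_genotypes,
    summarize_prevalence,
)
from .transmission import (
    TransmissionCall,
    TransmissionSummary,
    calls_to_frame,
    classify_transmissions,
    summarize_transmissions,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    inputs: dict[str, str]
    catalog_id: str
    call_modes: list[str]
    cohort_label: str
    seed: int | None = None
    tool_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class QCReport:
    """Input consistency report (report-only; never raises)."""

    n_genotype_records: int = 0
    n_no_calls: int = 0
    ploidy_issues: list[str] = field(default_factory=list)
    orphan_samples: list[str] = field(default_factory=list)
    family_issues: dict[str, list[str]] = field(default_factory=dict)
    no_call_rate_by_role: dict[str, float] = field(default_factory=dict)

    @property
    def no_call_rate(self) -> float:
        if self.n_genotype_records == 0:
            return 0.0
        return self.n_no_calls / self.n_genotype_records

    @property
    def genotyped_rate(self) -> float:
        return 1.0 - self.no_call_rate

    @property
    def is_clean(self) -> bool:
        return not (self.ploidy_issues or self.orphan_samples or self.family_issues)


def validate_inputs(
    genotypes: Mapping[str, RepeatGenotype],
    families: Mapping[str, Family],
    catalog: LocusCatalog | None = None,
) -> QCReport:
    """Cross-check genotypes against the pedigree: ploidy/sex mismatches,
    orphan samples, per-role no-call rates, family structure issues."""
    if catalog is None:
        catalog = default_catalog()
    report = QCReport(n_genotype_records=len(genotypes))
    roles = family_roles(families)
    role_totals: dict[str, list[int]] = {}
    ped_sex = {
        ind.sample_id: ind.sex
        for fam in families.values()
        for ind in fam.members.values()
    }
    for sid, gt in genotypes.items():
        if gt.is_no_call:
            report.n_no_calls += 1
        try:
            gt.validate_ploidy(catalog)
        except ValueError as exc:
            report.ploidy_issues.append(str(exc))
        if sid not in ped_sex:
            report.orphan_samples.append(sid)
        elif ped_sex[sid] is not gt.sex:
            report.ploidy_issues.append(
                f"{sid}: pedigree sex {ped_sex[sid].value} != genotype sex {gt.sex.value}"
            )
        role = roles.get(sid)
        if role is not None:
            cell = role_totals.setdefault(role.value, [0, 0])
            cell[0] += 1
            if gt.is_no_call:
                cell[1] += 1
    for fam in families.values():
        if fam.issues:
            report.family_issues[fam.family_id] = list(fam.issues)
    report.no_call_rate_by_role = {
        role: (nc / n if n else 0.0) for role, (n, nc) in sorted(role_totals.items())
    }
    return report


def family_roles(families: Mapping[str, Family]) -> dict[str, FamilyRole]:
    roles: dict[str, FamilyRole] = {}
    for fam in families.values():
        roles.update(fam.roles())
    return roles


def reconcile_dual_mode(
    primary: Mapping[str, RepeatGenotype],
    confirmatory: Mapping[str, RepeatGenotype],
    catalog: LocusCatalog | None = None,
) -> dict[str, RepeatGenotype]:
    """Re-evaluate primary-mode expanded flags under the confirmatory mode.

    Samples the primary call set flags as expanded are replaced by their
    confirmatory-mode genotype when one exists; everything else keeps its
    primary call.  The resulting carrier set is therefore a subset of the
    primary flags.
    """
    if catalog is None:
        catalog = default_catalog()
    out = dict(primary)
    for sid, gt in primary.items():
        if gt.is_no_call:
            continue
        if classify_individual(gt, catalog).is_expanded:
            confirm = confirmatory.get(sid)
            if confirm is not None and not confirm.is_no_call:
                out[sid] = confirm
            else:
                logger.warning("%s: flagged sample has no confirmatory call", sid)
    return out


@dataclass
class ReportBundle:
    manifest: RunManifest
    qc: QCReport
    prevalence: PrevalenceSummary
    hwe: HWEResult | None
    burden: dict[str, BurdenResult]
    transmission_calls: list[TransmissionCall]
    transmission: TransmissionSummary | None
    concordance: ConcordanceSummary | None
    final_genotypes: dict[str, RepeatGenotype]


def run_full_analysis(
    genotypes: Mapping[str, RepeatGenotype],
    families: Mapping[str, Family],
    catalog: LocusCatalog | None = None,
    confirmatory_genotypes: Mapping[str, RepeatGenotype] | None = None,
    cohort_label: str = "cohort",
    out_dir: str | Path | None = None,
    manifest: RunManifest | None = None,
) -> ReportBundle:
    """Execute the full screening pipeline on one cohort.

    Stages: input QC, optional dual-mode reconciliation, carrier
    classification and prevalence, female HWE QC, per-family transmission
    categorization, sex-stratified proband/sibling burden tests, and
    (with a confirmatory call set) mode concordance.  Stages whose inputs
    are missing are skipped with an explicit notice, never silently.
    """
    if catalog is None:
        catalog = default_catalog()
    if manifest is None:
        manifest = RunManifest(
            inputs={},
            catalog_id=catalog.locus_id,
            call_modes=sorted({g.call_mode.value for g in genotypes.values()}),
            cohort_label=cohort_label,
        )
    qc = validate_inputs(genotypes, families, catalog)

    concordance = None
    final = dict(genotypes)
    if confirmatory_genotypes:
        concordance = callset_concordance(
            genotypes.values(), confirmatory_genotypes.values(), catalog
        )
        final = reconcile_dual_mode(genotypes, confirmatory_genotypes, catalog)

    roles = family_roles(families)
    prevalence = summarize_prevalence(final, roles, catalog, cohort_id=cohort_label)

    hwe = None
    n_called_females = sum(
        1 for g in final.values() if g.sex.value == "female" and not g.is_no_call
    )
    if n_called_females:
        hwe = hwe_from_genotypes(final.values(), catalog)

    calls: list[TransmissionCall] = []
    transmission = None
    ready = [f for f in families.values() if f.analysis_ready]
    if ready:
        for fam in ready:
            calls.extend(classify_transmissions(fam, final, catalog))
        transmission = summarize_transmissions(
            calls, families, final, catalog, cohort_id=cohort_label
        )
    else:
        logger.warning("no analysis-ready families; transmission stage skipped")

    burden: dict[str, BurdenResult] = {}
    for label, proband_key, sibling_key in (
        ("male", "male_proband", "male_sibling"),
        ("female", "female_proband", "female_sibling"),
    ):
        pr = prevalence.rows.get(proband_key)
        sr = prevalence.rows.get(sibling_key)
        if pr and sr and pr.genotyped and sr.genotyped:
            burden[label] = burden_from_counts(
                pr.carriers, pr.noncarriers, sr.carriers, sr.noncarriers
            )

    bundle = ReportBundle(
        manifest=manifest,
        qc=qc,
        prevalence=prevalence,
        hwe=hwe,
        burden=burden,
        transmission_calls=calls,
        transmission=transmission,
        concordance=concordance,
        final_genotypes=final,
    )
    if out_dir is not None:
        write_reports(bundle, out_dir)
    return bundle


def write_reports(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(bundle.manifest.to_json() + "\n")
    bundle.prevalence.to_frame().to_csv(out / "prevalence.tsv", sep="\t", index=False)
    write_genotype_table(
        [bundle.final_genotypes[s] for s in sorted(bundle.final_genotypes)],
        out / "final_genotypes.tsv",
    )
    summary: dict = {
        "cohort": bundle.prevalence.cohort_id,
        "qc": {
            "n_genotype_records": bundle.qc.n_genotype_records,
            "no_call_rate": bundle.qc.no_call_rate,
            "ploidy_issues": bundle.qc.ploidy_issues,
            "orphan_samples": bundle.qc.orphan_samples,
            "family_issues": bundle.qc.family_issues,
        },
    }
    if bundle.hwe is not None:
        summary["hwe"] = {
            "n_females": bundle.hwe.n_females,
            "n_het": bundle.hwe.n_het,
            "n_hom_carrier": bundle.hwe.n_hom_carrier,
            "allele_freq": bundle.hwe.allele_freq,
            "chi2": bundle.hwe.chi2,
            "df": bundle.hwe.df,
            "p_value": bundle.hwe.p_value,
        }
    summary["burden"] = {
        label: {
            "table": [r.table.a, r.table.b, r.table.c, r.table.d],
            "odds_ratio": r.odds_ratio if r.odds_ratio_defined else str(r.odds_ratio),
            "p_value": r.p_value,
        }
        for label, r in bundle.burden.items()
    }
    if bundle.transmission is not None:
        bundle.transmission.to_frame().to_csv(
            out / "transmission.tsv", sep="\t", index=False
        )
        calls_to_frame(bundle.transmission_calls).to_csv(
            out / "transmission_calls.tsv", sep="\t", index=False
        )
        t = bundle.transmission
        summary["transmission"] = {
            "n_carrier_families": t.n_carrier_families,
            "n_offspring_in_carrier_families": t.n_offspring_in_carrier_families,
            "n_premutation_transmitted": t.n_premutation_transmitted,
            "n_de_novo": t.n_de_novo,
            "n_noninheriting": t.n_noninheriting,
            "n_x_violations": t.n_x_violations,
        }
    if bundle.concordance is not None:
        bundle.concordance.to_frame().to_csv(
            out / "concordance.tsv", sep="\t", index=False
        )
        summary["concordance"] = {
            "n_flagged_primary": bundle.concordance.n_flagged_a,
            "n_flagged_confirmatory": bundle.concordance.n_flagged_b,
            "n_class_discordant": bundle.concordance.n_class_discordant,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
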