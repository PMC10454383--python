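"""Synthetic ASD-family cohorts with known repeat-genotype ground truth.

Generates trio/quad nuclear families with X-linked CGG repeat genotypes:
founder alleles are drawn i.i.d. from a discrete length mixture (modes at
29-30 repeat units, a thin gray-zone band, and a rare premutation tail),
sons inherit one maternal allele, daughters inherit the paternal allele
plus one maternal allele, and each meiosis may perturb the transmitted
length through a simple instability model whose event probability grows
with the parental allele's range class.

Observed calls are the true genotypes passed through a measurement model
that mimics WGS-based repeat genotyping: occasional non-negative length
inflation whose probability grows with true length (strongest in the
"off-target" mode, damped in the "region-only" mode), confidence
intervals that broaden linearly with called length, and a small no-call
rate.  Every sample retains a :class:`TruthRecord`, so pipeline output
can be scored against ground truth exactly.

The generator emulates the statistical structure of family WGS cohorts
(male-skewed offspring, ~1% female premutation carriers, rare de novo
expansions); it does not model AGG interruptions, mosaicism, or
read-level artifacts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .catalog import LocusCatalog, RangeClass, classify_allele, default_catalog
from .io import (
    Affected,
    CallMode,
    Family,
    PedigreeIndividual,
    RepeatAllele,
    RepeatGenotype,
    Sex,
    write_eh_json,
    write_eh_vcf,
    write_genotype_table,
    write_pedigree,
)


class MeasurementMode(enum.Enum):
    NONE = "none"
    REGION_ONLY = "region_only"
    OFFTARGET = "offtarget"


_MODE_TO_CALL_MODE = {
    MeasurementMode.NONE: CallMode.EH_REGION_ONLY,
    MeasurementMode.REGION_ONLY: CallMode.EH_REGION_ONLY,
    MeasurementMode.OFFTARGET: CallMode.EH_OFFTARGET,
}


def default_allele_weights(
    premutation_weight: float = 0.005, gray_weight: float = 0.010
) -> dict[int, float]:
    """Founder allele-length mixture.

    Major modes at 29 and 30 repeat units with minor normal-range modes,
    a uniform gray-zone band (41-54), and a uniform premutation tail
    (55-120) whose default weight yields roughly 1% female carriers
    (2q with q = 0.005).
    """
    normal_modes = {
        20: 3, 23: 5, 27: 6, 29: 30, 30: 30, 31: 7, 32: 6, 33: 5, 36: 4, 39: 4,
    }
    normal_weight = 1.0 - premutation_weight - gray_weight
    total = sum(normal_modes.values())
    weights = {k: normal_weight * v / total for k, v in normal_modes.items()}
    gray_lengths = range(41, 55)
    for n in gray_lengths:
        weights[n] = gray_weight / len(gray_lengths)
    prem_lengths = range(55, 121)
    for n in prem_lengths:
        weights[n] = premutation_weight / len(prem_lengths)
    return weights


@dataclass(frozen=True)
class InstabilityModel:
    """Meiotic length-change model.

    An instability event fires with a class-dependent probability and
    adds a signed step; rare large positive steps generate de novo
    expansions from normal-range parental alleles.
    """

    event_prob_by_parent_class: Mapping[RangeClass, float] = field(
        default_factory=lambda: {
            RangeClass.NORMAL: 0.002,
            RangeClass.GRAY: 0.02,
            RangeClass.PREMUTATION: 0.05,
            RangeClass.FULL: 0.05,
        }
    )
    step_probs: Mapping[int, float] = field(
        default_factory=lambda: {
            -2: 0.10, -1: 0.25, 1: 0.30, 2: 0.15,
            30: 0.05, 40: 0.05, 50: 0.05, 60: 0.05,
        }
    )


@dataclass(frozen=True)
class MeasurementModel:
    """Length-dependent inflation plus CI broadening and no-calls.

    ``inflation_prob`` is piecewise in the true range class; inflation is
    always non-negative, so an observed call can over- but never
    under-flag an expanded allele.  CI half-width grows linearly in the
    called length above ``ci_anchor`` repeat units.
    """

    mode: MeasurementMode = MeasurementMode.OFFTARGET
    inflation_prob: Mapping[RangeClass, float] = field(
        default_factory=lambda: {
            RangeClass.NORMAL: 0.003,
            RangeClass.GRAY: 0.05,
            RangeClass.PREMUTATION: 0.30,
            RangeClass.FULL: 0.30,
        }
    )
    offtarget_step_range: tuple[int, int] = (20, 250)
    region_only_step_range: tuple[int, int] = (5, 40)
    ci_width_slope: float = 0.5
    ci_anchor: int = 30


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 500
    quad_fraction: float = 0.6
    offspring_sex_ratio_male: float = 0.69
    allele_weights: Mapping[int, float] = field(default_factory=default_allele_weights)
    instability: InstabilityModel = field(default_factory=InstabilityModel)
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    no_call_rate: float = 0.002
    locus_id: str = "FMR1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if not self.allele_weights:
            raise ValueError("allele mixture is empty")
        total = sum(self.allele_weights.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"allele mixture weights sum to {total}, expected 1")
        for p in (
            self.quad_fraction,
            self.offspring_sex_ratio_male,
            self.no_call_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class AlleleOrigin:
    origin: str  # "maternal" | "paternal"
    parent_allele: int
    delta: int
    de_novo: bool


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    family_id: str
    sex: Sex
    true_alleles: tuple[int, ...]
    origins: tuple[AlleleOrigin, ...]  # empty for founders

    @property
    def is_de_novo(self) -> bool:
        return any(o.de_novo for o in self.origins)


@dataclass
class Cohort:
    config: SimulationConfig
    families: dict[str, Family]
    truth_genotypes: dict[str, RepeatGenotype]
    observed_genotypes: dict[str, RepeatGenotype]
    truth_records: dict[str, TruthRecord]


def _draw_allele(rng: np.random.Generator, lengths: np.ndarray, probs: np.ndarray) -> int:
    return int(rng.choice(lengths, p=probs))


def _transmit(
    parent_allele: int,
    origin: str,
    rng: np.random.Generator,
    model: InstabilityModel,
    catalog: LocusCatalog,
) -> tuple[int, AlleleOrigin]:
    parent_class = classify_allele(parent_allele, catalog)
    child_allele = parent_allele
    if rng.random() < model.event_prob_by_parent_class.get(parent_class, 0.0):
        steps = np.array(list(model.step_probs.keys()))
        probs = np.array(list(model.step_probs.values()), dtype=float)
        probs /= probs.sum()
        child_allele = max(5, parent_allele + int(rng.choice(steps, p=probs)))
    prem = RangeClass.PREMUTATION
    de_novo = (
        classify_allele(child_allele, catalog) >= prem and parent_class < prem
    )
    return child_allele, AlleleOrigin(
        origin=origin,
        parent_allele=parent_allele,
        delta=child_allele - parent_allele,
        de_novo=de_novo,
    )


def _observe_allele(
    true_len: int,
    rng: np.random.Generator,
    model: MeasurementModel,
    catalog: LocusCatalog,
) -> RepeatAllele:
    obs = true_len
    if model.mode is not MeasurementMode.NONE:
        cls = classify_allele(true_len, catalog)
        if rng.random() < model.inflation_prob.get(cls, 0.0):
            lo, hi = (
                model.offtarget_step_range
                if model.mode is MeasurementMode.OFFTARGET
                else model.region_only_step_range
            )
            obs = true_len + int(rng.integers(lo, hi + 1))
    if model.mode is MeasurementMode.NONE:
        return RepeatAllele(obs, obs, obs)
    half = int(round(model.ci_width_slope * max(0, obs - model.ci_anchor) / 2))
    return RepeatAllele(obs, max(0, obs - half), obs + half)


def observe_genotypes(
    truth_genotypes: Mapping[str, RepeatGenotype],
    model: MeasurementModel,
    no_call_rate: float,
    seed: int,
    catalog: LocusCatalog | None = None,
) -> dict[str, RepeatGenotype]:
    """Apply a measurement model to true genotypes (deterministic in seed).

    Reusing one truth set with different models yields parallel call sets
    for concordance analysis.
    """
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(seed)
    call_mode = _MODE_TO_CALL_MODE[model.mode]
    out: dict[str, RepeatGenotype] = {}
    for sid in sorted(truth_genotypes):
        g = truth_genotypes[sid]
        if rng.random() < no_call_rate:
            out[sid] = RepeatGenotype(sid, g.locus_id, g.sex, (), call_mode)
            continue
        alleles = tuple(
            _observe_allele(n, rng, model, catalog) for n in g.lengths
        )
        out[sid] = RepeatGenotype(sid, g.locus_id, g.sex, alleles, call_mode)
    return out


def simulate_cohort(
    config: SimulationConfig, catalog: LocusCatalog | None = None
) -> Cohort:
    """Generate pedigree, true genotypes, observed calls and truth records.

    Deterministic for a fixed ``config.seed``.
    """
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(config.seed)
    lengths = np.array(sorted(config.allele_weights))
    probs = np.array([config.allele_weights[int(n)] for n in lengths], dtype=float)
    probs /= probs.sum()

    families: dict[str, Family] = {}
    truth_genotypes: dict[str, RepeatGenotype] = {}
    truth_records: dict[str, TruthRecord] = {}
    call_mode = _MODE_TO_CALL_MODE[config.measurement.mode]

    def add_truth(
        sid: str, fam_id: str, sex: Sex, alleles: tuple[int, ...],
        origins: tuple[AlleleOrigin, ...],
    ) -> None:
        truth_genotypes[sid] = RepeatGenotype(
            sid,
            config.locus_id,
            sex,
            tuple(RepeatAllele(n, n, n) for n in alleles),
            call_mode,
        )
        truth_records[sid] = TruthRecord(sid, fam_id, sex, alleles, origins)

    for i in range(config.n_families):
        fam_id = f"F{i:05d}"
        father_id, mother_id = f"{fam_id}_fa", f"{fam_id}_mo"
        father_allele = _draw_allele(rng, lengths, probs)
        mother_alleles = (
            _draw_allele(rng, lengths, probs),
            _draw_allele(rng, lengths, probs),
        )
        fam = Family(fam_id)
        fam.members[father_id] = PedigreeIndividual(
            fam_id, father_id, None, None, Sex.MALE, Affected.UNAFFECTED
        )
        fam.members[mother_id] = PedigreeIndividual(
            fam_id, mother_id, None, None, Sex.FEMALE, Affected.UNAFFECTED
        )
        add_truth(father_id, fam_id, Sex.MALE, (father_allele,), ())
        add_truth(
            mother_id, fam_id, Sex.FEMALE, tuple(sorted(mother_alleles)), ()
        )

        n_offspring = 2 if rng.random() < config.quad_fraction else 1
        for k in range(n_offspring):
            child_id = f"{fam_id}_c{k + 1}"
            sex = (
                Sex.MALE
                if rng.random() < config.offspring_sex_ratio_male
                else Sex.FEMALE
            )
            maternal_src = mother_alleles[int(rng.integers(0, 2))]
            mat_allele, mat_origin = _transmit(
                maternal_src, "maternal", rng, config.instability, catalog
            )
            if sex is Sex.MALE:
                alleles = (mat_allele,)
                origins = (mat_origin,)
            else:
                pat_allele, pat_origin = _transmit(
                    father_allele, "paternal", rng, config.instability, catalog
                )
                # store origins aligned with ascending allele order
                pairs = sorted(
                    [(pat_allele, pat_origin), (mat_allele, mat_origin)],
                    key=lambda t: t[0],
                )
                alleles = tuple(p[0] for p in pairs)
                origins = tuple(p[1] for p in pairs)
            fam.members[child_id] = PedigreeIndividual(
                fam_id,
                child_id,
                father_id,
                mother_id,
                sex,
                Affected.AFFECTED if k == 0 else Affected.UNAFFECTED,
            )
            add_truth(child_id, fam_id, sex, alleles, origins)
        families[fam_id] = fam

    observed = observe_genotypes(
        truth_genotypes,
        config.measurement,
        config.no_call_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
        catalog=catalog,
    )
    if config.measurement.mode is MeasurementMode.NONE:
        observed = dict(truth_genotypes)  # identity: observed equals truth
    return Cohort(
        config=config,
        families=families,
        truth_genotypes=truth_genotypes,
        observed_genotypes=observed,
        truth_records=truth_records,
    )


_TRUTH_HEADER = "sample_id\tfamily_id\tsex\ttrue_alleles\torigins\tde_novo"


def write_truth_table(records: Mapping[str, TruthRecord], path: str | Path) -> None:
    lines = [_TRUTH_HEADER]
    for sid in sorted(records):
        r = records[sid]
        origins = ";".join(
            f"{o.origin}:{o.parent_allele}:{o.delta:+d}:{int(o.de_novo)}"
            for o in r.origins
        )
        lines.append(
            f"{r.sample_id}\t{r.family_id}\t{r.sex.value}\t"
            f"{'/'.join(str(n) for n in r.true_alleles)}\t{origins or '.'}\t"
            f"{int(r.is_de_novo)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    per_sample_json: bool = False,
    extra_call_sets: Mapping[str, Mapping[str, RepeatGenotype]] | None = None,
) -> dict[str, Path]:
    """Write PED + observed VCF + genotype TSV + truth TSV into a directory.

    ``extra_call_sets`` (label -> genotypes) emits parallel VCFs, e.g. an
    off-target and a region-only call set for concordance testing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["ped"] = out / "cohort.ped"
    write_pedigree(cohort.families.values(), paths["ped"])

    observed = [cohort.observed_genotypes[s] for s in sorted(cohort.observed_genotypes)]
    paths["vcf"] = out / "observed.vcf"
    write_eh_vcf(observed, paths["vcf"])
    paths["table"] = out / "observed.tsv"
    write_genotype_table(observed, paths["table"])

    paths["truth"] = out / "truth.tsv"
    write_truth_table(cohort.truth_records, paths["truth"])

    if per_sample_json:
        json_dir = out / "json"
        json_dir.mkdir(exist_ok=True)
        for g in observed:
            write_eh_json([g], json_dir / f"{g.sample_id}.json")
        paths["json_dir"] = json_dir

    for label, calls in (extra_call_sets or {}).items():
        p = out / f"observed_{label}.vcf"
        write_eh_vcf([calls[s] for s in sorted(calls)], p)
        paths[f"vcf_{label}"] = p
    return paths
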