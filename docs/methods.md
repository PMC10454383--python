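# Methods

## Range classification

The locus catalog stores three inclusive upper bounds in repeat units
(FMR1 defaults: normal ≤ 40, gray ≤ 54, premutation ≤ 200; anything longer
is a full mutation). The boundary at 200 is treated as premutation-inclusive
(55–200), so 201 is the first full-mutation length; both conventions appear
in the clinical literature and the catalog is fully configurable, so a user
preferring full ≥ 200 can ship a catalog with `premutation_max = 199`.
Alleles below 5 repeat units are biologically implausible for this locus
but are classified as normal with a logged warning rather than rejected —
no analysis stage distinguishes a sub-normal class. An individual's
headline class is the class of the longer allele; "carrier"/"expanded"
throughout means at least one allele of premutation class or beyond.

## Genotype and pedigree I/O

Genotypes are normalized to sex-aware records (one allele for males at a
chrX locus, two for females, enforced at parse time) sorted ascending by
repeat count, with optional per-allele confidence intervals and a call-mode
tag (`eh_offtarget`, `eh_region_only`, `pcr`). Samples the genotyper skipped
are explicit no-call records; they count as "processed" but are excluded
from every denominator ("genotyped"). In the VCF representation the sample
sex is carried by call arity (`23` vs `29/70`, and `.` vs `./.` for
no-calls); PCR rows use the `Y/39` hemizygous notation and carry no CIs.
Genomic coordinates are passed through but never used — all analysis is on
repeat counts.

## Transmission inference

Repeat lengths drift between parent and offspring (germline instability
plus genotyping scatter), so parental origin is assigned by length
proximity rather than exact match:

- a son's single X allele is matched to the nearest maternal allele
  (never to the father);
- a daughter's two alleles are partitioned one-paternal/one-maternal by
  the cheaper of the two possible partitions under total absolute
  difference, the maternal slot taking the nearer of the mother's two
  alleles.

Ties break deterministically toward the smaller allele and are flagged
`ambiguous_match`; matches with |Δ| above a tolerance (default 5 repeat
units, configurable) are flagged `poor_match` but never dropped — this
reproduces the ability to count transmissions despite length drift while
surfacing dubious matches for audit. Origin labels are inherently
unidentifiable when both parents carry alleles of equal length; category
counts (below) are invariant to such label swaps, and this is what the
recovery tests assert.

Each offspring allele falls into one category, keyed by its **own**
measured class (the transmitted allele as observed in the offspring;
the matched parental allele's class is retained for audit):

- **premutation transmitted** — offspring allele ≥ premutation, matched
  parental allele ≥ premutation;
- **de novo expansion** — offspring allele ≥ premutation, matched parental
  allele below premutation; requires both parents genotyped (the claim is a
  pedigree-exclusion argument), so families with a no-called parent are
  skipped with a warning;
- **normal from carrier parent** — offspring allele below premutation while
  the transmitting parent carries a premutation allele; an apparent
  contraction (matched parental allele ≥ premutation, offspring below) is
  counted here with a `contraction` flag;
- plain normal transmission is not tabulated.

A son whose expanded allele is close (within tolerance) to his father's
premutation allele but far from any maternal allele is flagged
`x_linkage_violation` and reported separately — never counted as a
transmission or de novo event, since no chrX call path can pass a paternal
allele to a son. The summary's father→son rows are asserted to be zero on
every run.

Summary percentages use the number of genotyped offspring in
premutation-carrier families (families with ≥ 1 expanded member) as the
denominator; an empty cohort reports 0 with a logged warning. Families with
more than two offspring are handled per-offspring with no per-family
deduplication.

## Cohort statistics

**Burden tests** count carriers (individuals with ≥ 1 expanded allele), not
alleles, in a 2×2 proband/sibling table, stratified by sex because both
prevalence and ascertainment differ between males and females at a chrX
locus. The p-value is the standard two-sided Fisher exact test (sum of
hypergeometric probabilities ≤ that of the observed table, via
`scipy.stats.fisher_exact`; the test suite checks it against an exhaustive
exact-fraction enumeration oracle over all tables with total ≤ 25). The
odds ratio is reported as the sample cross-product *ad*/(*bc*) — not the
conditional MLE — because that is the convention the screening literature
prints; zero cells yield 0/∞/NaN with a `odds_ratio_defined` flag.
Combined-cohort tests pool the counts before testing. No multiple-testing
correction is applied.

**HWE QC** tests the female genotype classes (non-carrier / heterozygous /
homozygous carrier) against Hardy–Weinberg proportions with the carrier
allele frequency estimated from the same counts. Carrier females are
assumed heterozygous unless homozygous genotypes are present (homozygous
premutation females are vanishingly rare). The reported p-value uses df = 2
by default — the convention used in the screening reports this package
mirrors — although the statistic's sampling distribution with one estimated
parameter is asymptotically χ²(1); `df=1` is available as a parameter, and
the null-calibration tests assert the empirical mean of the statistic
against 1, which holds regardless of the reporting convention.

**Concordance** between two call sets compares longest-allele classes
per sample; "flagged" means class ≥ premutation. Samples present or called
in only one set are excluded with a warning.

The **parental-age Z-test** is a two-sample Z on group means with standard
error √(s₁²/n₁ + s₂²/n₂); under the null its p-values are uniform (checked
by simulation with a KS test).

**Dual-mode re-evaluation**: when both an off-target-style and a
region-only call set are supplied, samples flagged by the primary set are
re-classified from their region-only genotype. This mirrors the standard
workflow in which flagged samples are re-genotyped with off-target regions
disabled; it can confirm or downgrade a flag but never add carriers, so the
final carrier list is a subset of the primary flags (asserted in tests).

## Synthetic cohorts

The generator emulates the statistical structure of family-based ASD WGS
cohorts, with all parameters in `SimulationConfig`:

- **Structure**: `n_families` nuclear families; `quad_fraction` (default
  0.6) have two offspring, the rest one; the first offspring is the
  affected proband; offspring are male with probability 0.69 (the
  male-skew of ASD cohorts).
- **Founder alleles** i.i.d. from a discrete mixture: major modes at 29/30
  repeats with minor normal modes 20–39, a uniform gray band 41–54 (weight
  0.01), and a uniform premutation tail 55–120 (weight 0.005, giving
  ~1% female carriers as 2q).
- **Transmission**: sons draw one maternal allele uniformly; daughters copy
  the paternal allele and draw one maternal allele. An instability event
  fires with probability rising in the parental allele class (0.002 normal,
  0.02 gray, 0.05 premutation) and adds a signed step (mostly ±1–2, rarely
  +30…+60) — the rare large steps are what produce de novo expansions. These
  rates are pipeline-exercising placeholders, not biological estimates: no
  quantitative human instability model is fitted.
- **Measurement**: with probability rising in true class (0.003 / 0.05 /
  0.30), the called length is inflated by a non-negative step — uniform
  20–250 in `offtarget` mode, 5–40 in `region_only` mode (inflation-only by
  construction, so flagged carriers are always a superset of true carriers
  among called samples). CI half-width grows linearly with called length
  above 30 repeats (slope 0.5/unit), reproducing the broadening of
  bootstrap CIs with repeat length. A small no-call rate (default 0.002,
  matching ~99.8% genotyping rates) drops samples to explicit no-calls.
  `none` mode returns the truth unchanged.

Every sample keeps a truth record (true alleles, per-allele parental origin
and mutation delta, de novo flag), and truth is X-linked by construction.
What passing synthetic tests show: the pipeline's bookkeeping —
classification, origin assignment, category accounting, denominators,
reconciliation — is exact when measurement noise is off, and behaves
monotonically under the modeled inflation. What they do not show: robustness
to real-data features the generator omits (AGG interruptions, somatic
mosaicism, batch effects, non-paternity, genotyper-specific error profiles).

## Problem sizes and numerical choices

The recovery tests use 5,000-family cohorts (~18,000 samples, runs in a few
seconds) and the null-calibration checks use 50 seeds of 2,000 females —
large enough for the binomial/χ² expectations to be sharp at the asserted
4-standard-error tolerances. Fisher p-values are compared to the
enumeration oracle at 10⁻⁹ absolute; all other published-value checks are
at the printed precision (2 decimals for ORs and χ², 1–2 decimals for
percentages). Degenerate inputs (empty cohorts, zero denominators, zero
margins) report explicit zeros/None with warnings rather than raising,
except where an input is structurally invalid (negative counts, impossible
ploidy), which raises.

## Known limitations

- Origin assignment is length-based only; phasing from reads, mosaicism and
  maternal-age effects are out of scope.
- The published-count comparisons validate arithmetic and conventions, not
  individual-level genotyping; the underlying cohort data are
  access-restricted, so cohort-level results that require them (e.g.
  external-control comparisons with unpublished counts) are provided as
  machinery only.
- Single-locus analysis; the catalog supports other loci but the simulator
  models one locus per run.
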