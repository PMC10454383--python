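"""Repeat-range catalog and allele/individual classification.

The FMR1 CGG repeat is conventionally partitioned into four ranges by
repeat-unit count: normal (<=40), gray zone (41-54), premutation (55-200)
and full mutation (>=201).  All thresholds live in a :class:`LocusCatalog`
so that other short-tandem-repeat loci (or alternative boundary
conventions) can be screened with the same machinery; nothing downstream
hard-codes the FMR1 numbers.
"""

from __future__ import annotations

import enum
import functools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .io import RepeatGenotype

logger = logging.getLogger(__name__)

#: Alleles shorter than this are biologically implausible for FMR1 but are
#: still classified (as normal) with a warning rather than rejected.
MIN_PLAUSIBLE_REPEATS = 5


class ChromosomeType(enum.Enum):
    AUTOSOMAL = "autosomal"
    CHR_X = "chrX"


@functools.total_ordering
class RangeClass(enum.Enum):
    """Ordered repeat-range category: normal < gray < premutation < full."""

    NORMAL = "normal"
    GRAY = "gray"
    PREMUTATION = "premutation"
    FULL = "full"

    @property
    def rank(self) -> int:
        return _RANK[self]

    def __lt__(self, other: "RangeClass") -> bool:
        if not isinstance(other, RangeClass):
            return NotImplemented
        return self.rank < other.rank


_RANK = {
    RangeClass.NORMAL: 0,
    RangeClass.GRAY: 1,
    RangeClass.PREMUTATION: 2,
    RangeClass.FULL: 3,
}


@dataclass(frozen=True)
class LocusCatalog:
    """Range thresholds for one repeat locus.

    ``normal_max``, ``gray_max`` and ``premutation_max`` are inclusive upper
    bounds in repeat units; anything above ``premutation_max`` is a full
    mutation.
    """

    locus_id: str = "FMR1"
    chromosome_type: ChromosomeType = ChromosomeType.CHR_X
    repeat_unit: str = "CGG"
    normal_max: int = 40
    gray_max: int = 54
    premutation_max: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.normal_max < self.gray_max < self.premutation_max):
            raise ValueError(
                f"catalog thresholds must satisfy 0 < normal_max < gray_max "
                f"< premutation_max, got {self.normal_max}, {self.gray_max}, "
                f"{self.premutation_max}"
            )

    @property
    def is_x_linked(self) -> bool:
        return self.chromosome_type is ChromosomeType.CHR_X


def default_catalog() -> LocusCatalog:
    """The FMR1 CGG catalog (normal <=40, gray 41-54, premutation 55-200)."""
    return LocusCatalog()


def read_catalog(path: str | Path) -> dict[str, LocusCatalog]:
    """Read a catalog config file (TSV, one locus per row).

    Columns: locus_id, chromosome_type, repeat_unit, normal_max, gray_max,
    premutation_max.  Lines starting with ``#`` are comments.
    """
    catalogs: dict[str, LocusCatalog] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "locus_id":  # header
            continue
        if len(fields) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields")
        locus_id, chrom, unit, nmax, gmax, pmax = fields
        catalogs[locus_id] = LocusCatalog(
            locus_id=locus_id,
            chromosome_type=ChromosomeType(chrom),
            repeat_unit=unit,
            normal_max=int(nmax),
            gray_max=int(gmax),
            premutation_max=int(pmax),
        )
    if not catalogs:
        raise ValueError(f"{path}: no loci defined")
    return catalogs


def write_catalog(catalogs: Iterable[LocusCatalog], path: str | Path) -> None:
    lines = ["locus_id\tchromosome_type\trepeat_unit\tnormal_max\tgray_max\tpremutation_max"]
    for cat in catalogs:
        lines.append(
            f"{cat.locus_id}\t{cat.chromosome_type.value}\t{cat.repeat_unit}"
            f"\t{cat.normal_max}\t{cat.gray_max}\t{cat.premutation_max}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def classify_allele(length: int, catalog: LocusCatalog | None = None) -> RangeClass:
    """Classify a repeat-unit length into its range category.

    Boundaries are inclusive on both ends: normal <= normal_max,
    gray (normal_max, gray_max], premutation (gray_max, premutation_max],
    full > premutation_max.
    """
    if catalog is None:
        catalog = default_catalog()
    length = int(length)
    if length < 0:
        raise ValueError(f"repeat length must be non-negative, got {length}")
    if length < MIN_PLAUSIBLE_REPEATS:
        logger.warning(
            "allele of %d repeat units is below the plausible minimum (%d); "
            "classifying as normal",
            length,
            MIN_PLAUSIBLE_REPEATS,
        )
    if length <= catalog.normal_max:
        return RangeClass.NORMAL
    if length <= catalog.gray_max:
        return RangeClass.GRAY
    if length <= catalog.premutation_max:
        return RangeClass.PREMUTATION
    return RangeClass.FULL


@dataclass(frozen=True)
class CarrierStatus:
    """Per-individual carrier summary based on the longest allele."""

    sample_id: str
    longest_allele: int
    longest_class: RangeClass
    is_premutation_carrier: bool
    is_full_carrier: bool

    @property
    def is_expanded(self) -> bool:
        """True if any allele is in the premutation range or beyond."""
        return self.is_premutation_carrier or self.is_full_carrier


def classify_individual(
    genotype: "RepeatGenotype", catalog: LocusCatalog | None = None
) -> CarrierStatus:
    """Aggregate per-allele classes into a carrier status.

    The individual's headline class follows the longer-allele convention
    used in carrier screening: a female is a premutation carrier if either
    of her alleles falls in the premutation range.
    """
    if catalog is None:
        catalog = default_catalog()
    genotype.validate_ploidy(catalog)
    lengths = [a.repeat_units for a in genotype.alleles]
    if not lengths:
        raise ValueError(f"{genotype.sample_id}: no-call genotype cannot be classified")
    classes = [classify_allele(n, catalog) for n in lengths]
    longest = max(lengths)
    return CarrierStatus(
        sample_id=genotype.sample_id,
        longest_allele=longest,
        longest_class=classify_allele(longest, catalog),
        is_premutation_carrier=RangeClass.PREMUTATION in classes,
        is_full_carrier=RangeClass.FULL in classes,
    )
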