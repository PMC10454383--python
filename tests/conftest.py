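import pytest

from fmrscreen import (
    Affected,
    CallMode,
    Family,
    PedigreeIndividual,
    RepeatAllele,
    RepeatGenotype,
    Sex,
    default_catalog,
)


@pytest.fixture
def catalog():
    return default_catalog()


def make_genotype(sample_id, sex, lengths, mode=CallMode.EH_OFFTARGET, cis=None):
    """Build a RepeatGenotype from bare repeat counts (CIs optional)."""
    if cis is None:
        alleles = tuple(RepeatAllele(n) for n in lengths)
    else:
        alleles = tuple(RepeatAllele(n, lo, hi) for n, (lo, hi) in zip(lengths, cis))
    return RepeatGenotype(sample_id, "FMR1", sex, alleles, mode)


def make_trio_family(fam_id="fam1", proband_sex=Sex.MALE, sibling_sex=None):
    """A nuclear family: father, mother, affected proband, optional sibling."""
    fam = Family(fam_id)
    fam.members["fa"] = PedigreeIndividual(fam_id, "fa", None, None, Sex.MALE, Affected.UNAFFECTED)
    fam.members["mo"] = PedigreeIndividual(fam_id, "mo", None, None, Sex.FEMALE, Affected.UNAFFECTED)
    fam.members["pro"] = PedigreeIndividual(fam_id, "pro", "fa", "mo", proband_sex, Affected.AFFECTED)
    if sibling_sex is not None:
        fam.members["sib"] = PedigreeIndividual(fam_id, "sib", "fa", "mo", sibling_sex, Affected.UNAFFECTED)
    return fam


@pytest.fixture
def trio_family():
    return make_trio_family()
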