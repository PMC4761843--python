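import numpy as np
import pytest

from xtriad.triads import Haplotype, PhasedTriad, TriadGenotypes


def H(s: str) -> Haplotype:
    return Haplotype.from_string(s)


def make_phased(f: str, m1: str, m2: str, sex: str = "male", fid: str = "fam1") -> PhasedTriad:
    return PhasedTriad(
        family_id=fid,
        paternal=H(f),
        maternal_transmitted=H(m1),
        maternal_nontransmitted=H(m2),
        child_sex=sex,
    )


def make_triad(father, mother, child, sex="male", fid="fam1") -> TriadGenotypes:
    return TriadGenotypes(
        family_id=fid, father=father, mother=mother, child=child, child_sex=sex
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


@pytest.fixture
def phased_mixed() -> list[PhasedTriad]:
    """A small deterministic set of informative families of both sexes."""
    specs = [
        ("1100", "0000", "0100", "male"),
        ("0000", "1100", "0000", "female"),
        ("0100", "0000", "1100", "male"),
        ("0000", "0100", "0010", "female"),
        ("0010", "1000", "0000", "male"),
        ("1000", "0000", "0000", "female"),
        ("0000", "0010", "1000", "male"),
        ("0001", "0000", "0100", "female"),
    ]
    return [
        make_phased(f, m1, m2, sex, fid=f"fam{i + 1}")
        for i, (f, m1, m2, sex) in enumerate(specs)
    ]
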