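"""Pseudo-sibling risk sets for the conditional-logistic analysis.

Under parental haplotype exchangeability (PHE), conditioning on the
unordered set of three parental X haplotypes {F, M1, M2} makes each
same-sex child those haplotypes could produce equally likely a priori.
The observed affected child is compared, within family, against the two
pseudo-siblings of the same sex:

* affected son (carries M1): pseudo-brothers carry M2 and F;
* affected daughter (carries {F, M1}): pseudo-sisters carry {F, M2} and
  {M1, M2} — the other two unordered pairs of the parental haplotypes.

Each family is one conditional-logistic stratum with three alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import MendelianError, NoninformativeFamilyError
from .triads import MISSING, Haplotype, PhasedTriad, Sex, is_informative

#: An alternative is the multiset of haplotypes a (pseudo-)child carries,
#: stored as a sorted tuple: size 1 for males, size 2 for females.
Alternative = tuple[Haplotype, ...]


@dataclass(frozen=True)
class RiskSet:
    """One conditional-logistic stratum: observed child plus pseudo-siblings.

    ``alternatives`` holds the haplotype multisets of the possible same-sex
    children; ``case_index`` marks the observed child. The case is listed
    first and the pseudo-sibling alternatives follow in lexicographic order,
    so construction is reproducible; the conditional likelihood itself is
    order-invariant.
    """

    family_id: str
    child_sex: Sex
    alternatives: tuple[Alternative, ...]
    case_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.case_index < len(self.alternatives):
            raise ValueError("case_index out of range")

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    @property
    def case(self) -> Alternative:
        return self.alternatives[self.case_index]


def _sorted_alt(haps: Sequence[Haplotype]) -> Alternative:
    return tuple(sorted(haps))


def build_risk_set(phased: PhasedTriad) -> RiskSet:
    """Build the 3-alternative risk set of an informative family.

    Raises :class:`NoninformativeFamilyError` when F = M1 = M2 (the three
    alternatives would be indistinguishable and the stratum carries no
    information).
    """
    if not is_informative(phased):
        raise NoninformativeFamilyError(
            f"family {phased.family_id}: all three parental haplotypes identical"
        )
    f, m1, m2 = phased.parental_haplotypes()
    if phased.child_sex == "male":
        case = _sorted_alt([m1])
        controls = [_sorted_alt([m2]), _sorted_alt([f])]
    else:
        case = _sorted_alt([m1, f])
        controls = [_sorted_alt([m2, f]), _sorted_alt([m1, m2])]
    alternatives = (case, *sorted(controls))
    return RiskSet(
        family_id=phased.family_id,
        child_sex=phased.child_sex,
        alternatives=alternatives,
        case_index=0,
    )


def build_single_pseudo_sib(
    mother_genotype: Sequence[int] | None,
    son_haplotype: Sequence[int],
    *,
    father_haplotype: Sequence[int] | None = None,
    family_id: str = "",
) -> RiskSet:
    """Risk set for an affected son with one missing parent (optional feature).

    With the father missing, the mother's untransmitted haplotype
    (mother - son) is the single pseudo-brother. With the mother missing,
    the paternal haplotype serves as the pseudo-brother instead. Off by
    default in the scan; the main method requires complete triads.
    """
    son = Haplotype(son_haplotype)
    if mother_genotype is not None:
        mother = np.asarray(mother_genotype, dtype=np.int16)
        if (mother == MISSING).any() or MISSING in son:
            raise MendelianError(f"family {family_id}: missing calls in available members")
        control_vec = mother - np.asarray(son, dtype=np.int16)
        if ((control_vec < 0) | (control_vec > 1)).any():
            raise MendelianError(
                f"family {family_id}: mother minus son haplotype outside {{0, 1}}"
            )
        control = Haplotype(control_vec.tolist())
    elif father_haplotype is not None:
        control = Haplotype(father_haplotype)
    else:
        raise ValueError("one of mother_genotype or father_haplotype is required")
    if control == son:
        raise NoninformativeFamilyError(
            f"family {family_id}: pseudo-brother carries the same haplotype as the case"
        )
    return RiskSet(
        family_id=family_id,
        child_sex="male",
        alternatives=(_sorted_alt([son]), _sorted_alt([control])),
        case_index=0,
    )
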