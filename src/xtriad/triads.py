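"""Domain types for case-parent triads and deterministic X-haplotype phasing.

On the X chromosome, phase is fully determined for complete case-parent
triads: a father (or son) carries a single haplotype that is measured
directly, and subtracting the paternal haplotype from a daughter's summed
genotype recovers the maternally transmitted haplotype. Subtracting that
from the mother's genotype yields her untransmitted haplotype. Phasing is
therefore elementwise integer arithmetic with Mendelian-consistency checks,
and it is exact whenever no recombination occurred within the window (a
safe assumption for a handful of neighboring SNPs).

Genotypes are stored as minor-allele copy counts: {0, 1} for hemizygous
males, {0, 1, 2} for females, with ``MISSING`` (-1) for failed calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import MendelianError, MissingGenotypeError

#: Sentinel for a missing genotype call.
MISSING: int = -1

Sex = Literal["male", "female"]


class Haplotype(tuple):
    """An ordered vector of 0/1 minor-allele indicators over a SNP window.

    Immutable and hashable so it can key frequency tables and model columns.
    """

    def __new__(cls, alleles: Iterable[int]) -> "Haplotype":
        values = tuple(int(a) for a in alleles)
        if any(a not in (0, 1) for a in values):
            raise ValueError(f"haplotype alleles must be 0 or 1, got {values}")
        return super().__new__(cls, values)

    def __repr__(self) -> str:  # e.g. Haplotype('1100')
        return f"Haplotype('{''.join(str(a) for a in self)}')"

    @classmethod
    def from_string(cls, s: str) -> "Haplotype":
        return cls(int(c) for c in s)

    def to_string(self) -> str:
        return "".join(str(a) for a in self)


def _as_geno_array(values: Sequence[int]) -> np.ndarray:
    arr = np.asarray(values, dtype=np.int8)
    if arr.ndim != 1:
        raise ValueError("genotype vector must be one-dimensional")
    return arr


@dataclass(frozen=True)
class TriadGenotypes:
    """Unphased minor-allele copy counts for one father/mother/child triad.

    ``father`` and a male ``child`` are hemizygous (values in {0, 1});
    ``mother`` and a female ``child`` hold summed counts (values in
    {0, 1, 2}). ``MISSING`` marks failed calls.
    """

    family_id: str
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    child_sex: Sex

    def __post_init__(self) -> None:
        object.__setattr__(self, "father", _as_geno_array(self.father))
        object.__setattr__(self, "mother", _as_geno_array(self.mother))
        object.__setattr__(self, "child", _as_geno_array(self.child))
        n = len(self.father)
        if len(self.mother) != n or len(self.child) != n:
            raise ValueError("father, mother and child vectors must have equal length")
        if self.child_sex not in ("male", "female"):
            raise ValueError(f"child_sex must be 'male' or 'female', got {self.child_sex!r}")
        for name, arr, hemizygous in (
            ("father", self.father, True),
            ("mother", self.mother, False),
            ("child", self.child, self.child_sex == "male"),
        ):
            hi = 1 if hemizygous else 2
            bad = (arr != MISSING) & ((arr < 0) | (arr > hi))
            if bad.any():
                raise ValueError(f"{name} genotypes out of range [0, {hi}]: {arr}")

    @property
    def n_loci(self) -> int:
        return len(self.father)

    def window(self, start: int, width: int) -> "TriadGenotypes":
        """Slice a contiguous window of loci (panel order)."""
        sl = slice(start, start + width)
        return TriadGenotypes(
            family_id=self.family_id,
            father=self.father[sl],
            mother=self.mother[sl],
            child=self.child[sl],
            child_sex=self.child_sex,
        )


@dataclass(frozen=True)
class PhasedTriad:
    """The three parental X haplotypes of a triad with transmission labels.

    ``paternal`` (F) is the father's single haplotype, ``maternal_transmitted``
    (M1) the maternal haplotype inherited by the affected child, and
    ``maternal_nontransmitted`` (M2) the mother's other haplotype. This triple
    plus the child's sex is the sufficient statistic of the method.
    """

    family_id: str
    paternal: Haplotype
    maternal_transmitted: Haplotype
    maternal_nontransmitted: Haplotype
    child_sex: Sex

    def __post_init__(self) -> None:
        w = len(self.paternal)
        if len(self.maternal_transmitted) != w or len(self.maternal_nontransmitted) != w:
            raise ValueError("the three haplotypes must have equal width")

    @property
    def width(self) -> int:
        return len(self.paternal)

    def parental_haplotypes(self) -> tuple[Haplotype, Haplotype, Haplotype]:
        """(F, M1, M2) in that order."""
        return (self.paternal, self.maternal_transmitted, self.maternal_nontransmitted)

    def child_haplotypes(self) -> tuple[Haplotype, ...]:
        """The haplotype(s) the affected child carries."""
        if self.child_sex == "male":
            return (self.maternal_transmitted,)
        return (self.paternal, self.maternal_transmitted)

    def to_genotypes(self) -> TriadGenotypes:
        """Degrade back to observable (phase-ambiguous) genotype counts."""
        f = np.asarray(self.paternal, dtype=np.int8)
        m1 = np.asarray(self.maternal_transmitted, dtype=np.int8)
        m2 = np.asarray(self.maternal_nontransmitted, dtype=np.int8)
        child = m1 if self.child_sex == "male" else f + m1
        return TriadGenotypes(
            family_id=self.family_id,
            father=f,
            mother=m1 + m2,
            child=child,
            child_sex=self.child_sex,
        )


def _check_binary(vec: np.ndarray, family_id: str, role: str) -> Haplotype:
    if ((vec < 0) | (vec > 1)).any():
        raise MendelianError(
            f"family {family_id}: inferred {role} haplotype {vec.tolist()} "
            "has allele counts outside {0, 1}"
        )
    return Haplotype(vec.tolist())


def phase_triad(triad: TriadGenotypes) -> PhasedTriad:
    """Phase a complete triad by haplotype subtraction.

    Males: M1 = child, M2 = mother - child, F = father.
    Females: M1 = child - father, M2 = mother - M1, F = father.

    Raises
    ------
    MissingGenotypeError
        If any member has a missing call at any locus in the window.
    MendelianError
        If any subtraction leaves an allele count outside {0, 1}
        (a genotyping inconsistency; the family should be excluded).
    """
    for role, arr in (("father", triad.father), ("mother", triad.mother), ("child", triad.child)):
        if (arr == MISSING).any():
            raise MissingGenotypeError(
                f"family {triad.family_id}: missing {role} genotype in window"
            )
    father = triad.father.astype(np.int16)
    mother = triad.mother.astype(np.int16)
    child = triad.child.astype(np.int16)

    paternal = _check_binary(father, triad.family_id, "paternal")
    if triad.child_sex == "male":
        m1 = child
    else:
        m1 = child - father
    m1_h = _check_binary(m1, triad.family_id, "maternal transmitted")
    m2_h = _check_binary(mother - m1, triad.family_id, "maternal nontransmitted")
    return PhasedTriad(
        family_id=triad.family_id,
        paternal=paternal,
        maternal_transmitted=m1_h,
        maternal_nontransmitted=m2_h,
        child_sex=triad.child_sex,
    )


def is_informative(phased: PhasedTriad) -> bool:
    """A family is noninformative iff all three parental haplotypes coincide."""
    f, m1, m2 = phased.parental_haplotypes()
    return not (f == m1 == m2)


def phase_window_arrays(
    father: np.ndarray,
    mother: np.ndarray,
    child: np.ndarray,
    is_male: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized phasing over families: returns (F, M1, M2, valid).

    Inputs are (n_families, width) count matrices (``MISSING`` allowed) and a
    boolean child-sex vector. Rows with missing calls or Mendelian
    inconsistencies are flagged ``valid=False`` instead of raising, matching
    the window-local exclusion rule of the scan. Equivalent to
    :func:`phase_triad` row by row (property-tested).
    """
    father = father.astype(np.int16)
    mother = mother.astype(np.int16)
    child = child.astype(np.int16)
    m1 = np.where(is_male[:, None], child, child - father)
    m2 = mother - m1
    complete = ((father != MISSING) & (mother != MISSING) & (child != MISSING)).all(axis=1)
    ok = lambda h: ((h >= 0) & (h <= 1)).all(axis=1)  # noqa: E731
    valid = complete & ok(father) & ok(m1) & ok(m2)
    return father, m1, m2, valid
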