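"""Testing parental haplotype exchangeability (PHE) and its sex decomposition.

PHE states that, in the source population, each of the three X haplotypes
carried by a couple is equally likely to be the father's single haplotype.
It is tested with the same conditional-logistic machinery as the
association scan, but with the father's haplotype treated as the "case"
and the mother's two haplotypes as the matched controls, each alternative
carrying exactly one haplotype ("single" dosage coding). The test is valid
under the global null of no haplotype effects and no maternally-mediated
effects.

A rejection need not mean PHE fails in the population: a true fetal
(transmitted-haplotype) effect induces a parental asymmetry that reverses
with the sex of the affected child — mothers of affected boys and fathers
of affected girls are enriched for a causative haplotype — whereas a
maternally-mediated effect (or genuine PHE violation, e.g. asymmetric
mating) enriches mothers regardless of offspring sex. Augmenting the PHE
model with haplotype x offspring-sex interactions therefore separates the
two signatures: a significant interaction is consistent with a fetal
effect, a significant main asymmetry without interaction with a maternal
effect or a PHE violation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .clr import (
    HaplotypeCodebook,
    LRTResult,
    SexSubset,
    lrt,
    lrt_arrays,
    risk_sets_to_arrays,
)
from .errors import DegenerateWindowError, NoninformativeFamilyError
from .pseudo import RiskSet
from .triads import PhasedTriad, is_informative


def phe_risk_set(phased: PhasedTriad) -> RiskSet:
    """The PHE stratum: case {F} vs controls {M1} and {M2}, single coding.

    Under PHE each alternative is the father's with probability 1/3.
    """
    if not is_informative(phased):
        raise NoninformativeFamilyError(
            f"family {phased.family_id}: all three parental haplotypes identical"
        )
    f, m1, m2 = phased.parental_haplotypes()
    controls = sorted([(m1,), (m2,)])
    return RiskSet(
        family_id=phased.family_id,
        child_sex=phased.child_sex,
        alternatives=((f,), *controls),
        case_index=0,
    )


def phe_risk_sets(phased_triads: Iterable[PhasedTriad]) -> list[RiskSet]:
    """PHE strata for every informative family."""
    return [phe_risk_set(ph) for ph in phased_triads if is_informative(ph)]


def phe_lrt(
    phased_triads: Sequence[PhasedTriad],
    codebook: HaplotypeCodebook,
    sex_subset: SexSubset = "both",
) -> LRTResult:
    """Global LRT of parental haplotype exchangeability for one window.

    Same deviance machinery as the association test, df = number of common
    haplotypes - 1. Without interaction terms the test does not depend on
    offspring sex.
    """
    return lrt(phe_risk_sets(phased_triads), codebook, coding="single", sex_subset=sex_subset)


@dataclass(frozen=True)
class PHESexDecomposition:
    """Main-asymmetry and sex-interaction components of a PHE violation."""

    main: LRTResult
    interaction: LRTResult
    flag: str  # qualitative reading of the two component tests


def _interpret(main_p: float, interaction_p: float, alpha: float) -> str:
    if np.isfinite(interaction_p) and interaction_p < alpha:
        return "consistent with fetal effect"
    if np.isfinite(main_p) and main_p < alpha:
        return "consistent with maternal effect or PHE violation"
    return "consistent with PHE"


def phe_sex_decomposition(
    phased_triads: Sequence[PhasedTriad],
    codebook: HaplotypeCodebook,
    alpha: float = 0.05,
) -> PHESexDecomposition:
    """Decompose a PHE signal by offspring sex.

    Fits the PHE model with haplotype x offspring-sex interaction columns
    and reports the interaction LRT (df = number of model columns) next to
    the main-effect PHE LRT. The flags are qualitative guides, not
    automated conclusions: a fetal effect reverses the parental asymmetry
    between boys' and girls' families, a maternal effect does not.
    """
    risk_sets = phe_risk_sets(phased_triads)
    sexes = {rs.child_sex for rs in risk_sets}
    if sexes != {"male", "female"}:
        raise DegenerateWindowError(
            "sex decomposition requires informative families of both offspring sexes"
        )
    main = lrt(risk_sets, codebook, coding="single")

    X, mask, case_idx = risk_sets_to_arrays(risk_sets, codebook, coding="single")
    p = X.shape[2]
    is_boy = np.array([rs.child_sex == "male" for rs in risk_sets], dtype=float)
    X_full = np.concatenate([X, X * is_boy[:, None, None]], axis=2)
    interaction = lrt_arrays(
        X_full, mask, case_idx, null_columns=list(range(p)), df=p,
        window_id=codebook.window_id,
    )
    flag = _interpret(main.p_value, interaction.p_value, alpha)
    return PHESexDecomposition(main=main, interaction=interaction, flag=flag)


# ---------------------------------------------------------------------------
# Fast array path (simulation studies of the PHE test)
# ---------------------------------------------------------------------------

def phe_arrays(
    F: np.ndarray, M1: np.ndarray, M2: np.ndarray, column_of: np.ndarray, n_columns: int
) -> np.ndarray:
    """Dosage tensor (n, 3, p) of PHE strata from haplotype codes; the
    father's alternative is at index 0. Matches :func:`phe_risk_set` +
    single coding (tested)."""
    n = F.shape[0]
    X = np.zeros((n, 3, n_columns))
    alt = np.stack([F, M1, M2], axis=1)
    cols = column_of[alt].ravel()
    rows = np.repeat(np.arange(n), 3)
    alts = np.tile(np.arange(3), n)
    ok = cols >= 0
    np.add.at(X, (rows[ok], alts[ok], cols[ok]), 1.0)
    return X


def phe_lrt_codes(
    F: np.ndarray,
    M1: np.ndarray,
    M2: np.ndarray,
    width: int,
    rare_threshold: float = 0.01,
) -> LRTResult:
    """PHE LRT straight from haplotype-code arrays (fast simulation path)."""
    from .sim import codebook_from_codes

    informative = ~((F == M1) & (M1 == M2))
    Fc, M1c, M2c = F[informative], M1[informative], M2[informative]
    parental = np.concatenate([Fc, M1c, M2c])
    column_of, n_common, has_rare, _ = codebook_from_codes(parental, width, rare_threshold)
    p = n_common - 1 + (1 if has_rare else 0)
    X = phe_arrays(Fc, M1c, M2c, column_of, p)
    mask = np.ones((X.shape[0], 3), dtype=bool)
    case_idx = np.zeros(X.shape[0], dtype=np.intp)
    null_cols = [p - 1] if has_rare else []
    return lrt_arrays(X, mask, case_idx, null_cols, df=n_common - 1)


def phe_decomposition_codes(
    F: np.ndarray,
    M1: np.ndarray,
    M2: np.ndarray,
    is_male: np.ndarray,
    width: int,
    rare_threshold: float = 0.01,
) -> tuple[LRTResult, LRTResult]:
    """(main, interaction) PHE tests from code arrays (fast simulation path)."""
    from .sim import codebook_from_codes

    informative = ~((F == M1) & (M1 == M2))
    Fc, M1c, M2c = F[informative], M1[informative], M2[informative]
    boy = is_male[informative].astype(float)
    parental = np.concatenate([Fc, M1c, M2c])
    column_of, n_common, has_rare, _ = codebook_from_codes(parental, width, rare_threshold)
    p = n_common - 1 + (1 if has_rare else 0)
    X = phe_arrays(Fc, M1c, M2c, column_of, p)
    mask = np.ones((X.shape[0], 3), dtype=bool)
    case_idx = np.zeros(X.shape[0], dtype=np.intp)
    null_cols = [p - 1] if has_rare else []
    main = lrt_arrays(X, mask, case_idx, null_cols, df=n_common - 1)
    X_full = np.concatenate([X, X * boy[:, None, None]], axis=2)
    interaction = lrt_arrays(X_full, mask, case_idx, list(range(p)), df=p)
    return main, interaction
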