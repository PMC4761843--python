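"""Triad simulator: null (HWE and stratified) and risk scenarios for the X.

Families are generated under parental haplotype exchangeability by
construction: three haplotypes are drawn i.i.d. from a subpopulation's
haplotype distribution and randomly allocated, one to the father and two
to the mother; the maternal transmission is a fair coin. Ascertainment of
an *affected* child is by rejection sampling with acceptance probability
proportional to

    baseline(subpopulation) x RR_child(haplotypes, sex) x RR_maternal(mother)

normalized by the global maximum, so only risk ratios (not absolute
baseline risks) matter.

Two reference subpopulations are built in: per-locus minor-allele
frequencies of 0.3 at each of 4 SNPs (subpopulation 1) and 0.2
(subpopulation 2), with haplotype frequencies given by independence
across loci — e.g. haplotype 1100 has frequency 0.3*0.3*0.7*0.7 = 0.0441
in subpopulation 1. The stratified null mixes the two with a 4-fold
baseline-risk ratio. Risk scenarios designate 1100 (and, in scenarios B
and C, also 1101) as risk haplotypes with a log-additive dose model in
girls: a boy's relative risk R_B equals a two-copy girl's R_G2, and a
one-copy girl has R_G1 = sqrt(R_G2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .clr import lrt_arrays
from .errors import ConfigError
from .triads import Haplotype, PhasedTriad, TriadGenotypes, phase_window_arrays

ScenarioName = Literal["null-hwe", "null-stratified", "A", "B", "C"]

#: Default per-locus minor-allele frequencies of the two reference
#: subpopulations (4 SNPs each; haplotype frequencies are their products).
SUBPOP1_LOCUS_MAF = (0.3, 0.3, 0.3, 0.3)
SUBPOP2_LOCUS_MAF = (0.2, 0.2, 0.2, 0.2)

RISK_HAPLOTYPE = Haplotype.from_string("1100")
SECOND_RISK_HAPLOTYPE = Haplotype.from_string("1101")


def hwe_haplotype_frequencies(locus_maf: Sequence[float]) -> dict[Haplotype, float]:
    """Haplotype frequencies under independence across loci (HWE within a
    subpopulation): the product of per-locus allele frequencies."""
    w = len(locus_maf)
    freqs: dict[Haplotype, float] = {}
    for code in range(2**w):
        bits = [(code >> (w - 1 - i)) & 1 for i in range(w)]
        p = 1.0
        for b, maf in zip(bits, locus_maf):
            p *= maf if b else 1.0 - maf
        freqs[Haplotype(bits)] = p
    return freqs


def subpopulation_frequencies() -> tuple[dict[Haplotype, float], dict[Haplotype, float]]:
    """The two built-in subpopulation haplotype-frequency tables."""
    return (
        hwe_haplotype_frequencies(SUBPOP1_LOCUS_MAF),
        hwe_haplotype_frequencies(SUBPOP2_LOCUS_MAF),
    )


def rescale_frequencies(
    base_frequencies: Mapping[Haplotype, float],
    risk_haplotypes: Iterable[Haplotype],
    target_total: float,
) -> dict[Haplotype, float]:
    """Set the risk haplotypes' total frequency, preserving their internal
    ratio, and rescale all remaining haplotypes by a common factor so the
    distribution still sums to one."""
    risk = list(risk_haplotypes)
    if not 0 < target_total < 1:
        raise ConfigError(f"target_total must be in (0, 1), got {target_total}")
    risk_base = sum(base_frequencies[h] for h in risk)
    if risk_base <= 0:
        raise ConfigError("risk haplotypes have zero total base frequency")
    other_scale = (1.0 - target_total) / (1.0 - risk_base)
    out = {}
    for h, f in base_frequencies.items():
        if h in risk:
            out[h] = f * target_total / risk_base
        else:
            out[h] = f * other_scale
    return out


@dataclass(frozen=True)
class RiskTriple:
    """Relative risks of one haplotype: boys (R_B), one-copy girls (R_G1),
    two-copy girls (R_G2)."""

    boy: float
    girl_one_copy: float
    girl_two_copies: float

    @classmethod
    def log_additive(cls, r: float) -> "RiskTriple":
        """R_B = R_G2 = r with R_G1 = sqrt(r) (one-copy girls halfway on the
        log scale), the dose model used throughout the built-in scenarios."""
        return cls(boy=r, girl_one_copy=math.sqrt(r), girl_two_copies=r)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one study's worth of affected triads."""

    subpop_frequencies: tuple[dict[Haplotype, float], ...]
    subpop_mix: float = 1.0  # proportion of families from subpopulation 1
    baseline_risk_ratio: float = 1.0  # baseline disease risk, subpop 2 vs 1
    risk_map: dict[Haplotype, RiskTriple] = field(default_factory=dict)
    maternal_risk_map: dict[Haplotype, float] = field(default_factory=dict)
    n_families: int = 1000
    seed: int | None = None
    sex_ratio: float = 0.5  # proportion of affected children who are boys

    def __post_init__(self) -> None:
        if not self.subpop_frequencies:
            raise ConfigError("at least one subpopulation is required")
        widths = set()
        for freqs in self.subpop_frequencies:
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ConfigError("subpopulation frequencies must sum to 1")
            if any(f < 0 for f in freqs.values()):
                raise ConfigError("negative haplotype frequency")
            widths.update(len(h) for h in freqs)
        if len(widths) != 1:
            raise ConfigError("all haplotypes must share one window width")
        if not 0 <= self.subpop_mix <= 1:
            raise ConfigError("subpop_mix must be in [0, 1]")
        if not 0 < self.sex_ratio < 1:
            raise ConfigError("sex_ratio must be in (0, 1)")
        if self.baseline_risk_ratio <= 0:
            raise ConfigError("baseline_risk_ratio must be positive")

    @property
    def width(self) -> int:
        return len(next(iter(self.subpop_frequencies[0])))


# ---------------------------------------------------------------------------
# Haplotype <-> integer-code helpers (fast path)
# ---------------------------------------------------------------------------

def hap_to_code(h: Haplotype) -> int:
    code = 0
    for b in h:
        code = (code << 1) | b
    return code


def code_to_hap(code: int, width: int) -> Haplotype:
    return Haplotype((code >> (width - 1 - i)) & 1 for i in range(width))


def _code_bits(width: int) -> np.ndarray:
    """(2^width, width) lookup table of allele vectors."""
    codes = np.arange(2**width)
    shifts = np.arange(width - 1, -1, -1)
    return ((codes[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def _subpop_tables(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-subpopulation cumulative haplotype-code distributions."""
    w = config.width
    cum = np.zeros((len(config.subpop_frequencies), 2**w))
    for s, freqs in enumerate(config.subpop_frequencies):
        probs = np.zeros(2**w)
        for h, f in freqs.items():
            probs[hap_to_code(h)] = f
        cum[s] = np.cumsum(probs)
    codes = np.arange(2**w)
    return codes, cum


def _risk_arrays(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-code relative risks: (boy, girl one copy, girl two copies, maternal)."""
    n = 2 ** config.width
    r_boy = np.ones(n)
    r_g1 = np.ones(n)
    r_g2 = np.ones(n)
    r_mat = np.ones(n)
    for h, t in config.risk_map.items():
        c = hap_to_code(h)
        r_boy[c], r_g1[c], r_g2[c] = t.boy, t.girl_one_copy, t.girl_two_copies
    for h, r in config.maternal_risk_map.items():
        r_mat[hap_to_code(h)] = r
    return r_boy, r_g1, r_g2, r_mat


def draw_families(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` ascertained (affected-child) families.

    Returns haplotype-code arrays (F, M1, M2) and a boolean ``is_male``
    vector. PHE holds by construction: the father's haplotype is a
    uniformly chosen one of the three i.i.d. draws.
    """
    _, cum = _subpop_tables(config)
    r_boy, r_g1, r_g2, r_mat = _risk_arrays(config)
    baselines = np.array([1.0, config.baseline_risk_ratio])[: len(config.subpop_frequencies)]
    girl_max = max(float(r_g1.max()) ** 2, float(r_g2.max()))
    max_weight = float(baselines.max()) * max(1.0, float(r_boy.max()), girl_max) * float(
        r_mat.max()
    ) ** 2

    outF, outM1, outM2, out_male = [], [], [], []
    remaining = n
    while remaining > 0:
        batch = max(64, int(remaining * 1.6))
        subpop = (rng.random(batch) >= config.subpop_mix).astype(np.intp)
        if len(config.subpop_frequencies) == 1:
            subpop[:] = 0
        u = rng.random((batch, 3))
        haps = np.empty((batch, 3), dtype=np.intp)
        for s in range(cum.shape[0]):
            sel = subpop == s
            if sel.any():
                haps[sel] = np.searchsorted(cum[s], u[sel], side="right")
        # random allocation: one haplotype to the father, two to the mother
        father_slot = rng.integers(0, 3, size=batch)
        rows = np.arange(batch)
        F = haps[rows, father_slot]
        rest = np.stack(
            [haps[rows, (father_slot + 1) % 3], haps[rows, (father_slot + 2) % 3]], axis=1
        )
        transmit = rng.integers(0, 2, size=batch)
        M1 = rest[rows, transmit]
        M2 = rest[rows, 1 - transmit]
        is_male = rng.random(batch) < config.sex_ratio
        rr_child = np.where(
            is_male,
            r_boy[M1],
            np.where(F == M1, r_g2[M1], r_g1[F] * r_g1[M1]),
        )
        weight = baselines[subpop] * rr_child * r_mat[M1] * r_mat[M2]
        accept = rng.random(batch) < weight / max_weight
        take = min(int(accept.sum()), remaining)
        idx = np.flatnonzero(accept)[:take]
        outF.append(F[idx])
        outM1.append(M1[idx])
        outM2.append(M2[idx])
        out_male.append(is_male[idx])
        remaining -= take
    return (
        np.concatenate(outF),
        np.concatenate(outM1),
        np.concatenate(outM2),
        np.concatenate(out_male),
    )


def draw_family(config: SimulationConfig, rng: np.random.Generator) -> PhasedTriad:
    """Draw a single ascertained family as a :class:`PhasedTriad`."""
    F, M1, M2, male = draw_families(config, rng, 1)
    w = config.width
    return PhasedTriad(
        family_id="sim",
        paternal=code_to_hap(int(F[0]), w),
        maternal_transmitted=code_to_hap(int(M1[0]), w),
        maternal_nontransmitted=code_to_hap(int(M2[0]), w),
        child_sex="male" if male[0] else "female",
    )


def draw_phased_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[PhasedTriad]:
    """Draw ``config.n_families`` families with their phased truth attached."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    F, M1, M2, male = draw_families(config, rng, config.n_families)
    w = config.width
    return [
        PhasedTriad(
            family_id=f"fam{i + 1:05d}",
            paternal=code_to_hap(int(F[i]), w),
            maternal_transmitted=code_to_hap(int(M1[i]), w),
            maternal_nontransmitted=code_to_hap(int(M2[i]), w),
            child_sex="male" if male[i] else "female",
        )
        for i in range(config.n_families)
    ]


def make_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[TriadGenotypes]:
    """Draw a dataset and degrade it to observable (unphased) genotypes,
    so downstream analyses exercise the full phasing path. Deterministic
    given ``config.seed`` (or the supplied generator)."""
    return [ph.to_genotypes() for ph in draw_phased_dataset(config, rng)]


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def scenario_config(
    scenario: ScenarioName,
    n_families: int = 1000,
    seed: int | None = None,
    risk_frequency: float | None = None,
    sex_ratio: float = 0.5,
    subpop_mix: float = 0.5,
) -> SimulationConfig:
    """Build the configuration of one named study scenario.

    ``risk_frequency`` rescales the total frequency of the risk
    haplotype(s) (preserving the built-in 0.0441:0.0189 ratio when there
    are two) as in the power study; None keeps the base table.
    """
    sub1, sub2 = subpopulation_frequencies()
    if scenario == "null-hwe":
        return SimulationConfig(
            subpop_frequencies=(sub1,), n_families=n_families, seed=seed, sex_ratio=sex_ratio
        )
    if scenario == "null-stratified":
        return SimulationConfig(
            subpop_frequencies=(sub1, sub2),
            subpop_mix=subpop_mix,
            baseline_risk_ratio=4.0,
            n_families=n_families,
            seed=seed,
            sex_ratio=sex_ratio,
        )
    if scenario == "A":
        risk_map = {RISK_HAPLOTYPE: RiskTriple.log_additive(1.5)}
        risk_haps = [RISK_HAPLOTYPE]
    elif scenario == "B":
        risk_map = {
            RISK_HAPLOTYPE: RiskTriple.log_additive(1.5),
            SECOND_RISK_HAPLOTYPE: RiskTriple.log_additive(1.2),
        }
        risk_haps = [RISK_HAPLOTYPE, SECOND_RISK_HAPLOTYPE]
    elif scenario == "C":
        risk_map = {
            RISK_HAPLOTYPE: RiskTriple.log_additive(1.5),
            SECOND_RISK_HAPLOTYPE: RiskTriple.log_additive(1 / 1.2),
        }
        risk_haps = [RISK_HAPLOTYPE, SECOND_RISK_HAPLOTYPE]
    else:
        raise ConfigError(f"unknown scenario {scenario!r}")
    freqs = sub1
    if risk_frequency is not None:
        freqs = rescale_frequencies(sub1, risk_haps, risk_frequency)
    return SimulationConfig(
        subpop_frequencies=(freqs,),
        risk_map=risk_map,
        n_families=n_families,
        seed=seed,
        sex_ratio=sex_ratio,
    )


# ---------------------------------------------------------------------------
# Vectorized study pipeline
# ---------------------------------------------------------------------------

def codebook_from_codes(
    parental_codes: np.ndarray, width: int, threshold: float
) -> tuple[np.ndarray, int, bool, np.ndarray]:
    """Integer-code analogue of ``build_codebook``.

    Returns (column_of, n_common, has_rare, common_codes): ``column_of[c]``
    is the model-column index of haplotype code ``c`` (-1 for the reference,
    the last column for pooled-rare codes, -9 for unobserved). Ordering
    matches the object codebook (decreasing frequency, haplotype order).
    """
    counts = np.bincount(parental_codes, minlength=2**width)
    total = counts.sum()
    freqs = counts / total
    observed = np.flatnonzero(counts)
    common = observed[freqs[observed] >= threshold]
    order = np.lexsort((common, -freqs[common]))
    common = common[order]
    rare = observed[freqs[observed] < threshold]
    column_of = np.full(2**width, -9, dtype=np.intp)
    column_of[common[0]] = -1  # reference: most frequent common haplotype
    for j, c in enumerate(common[1:]):
        column_of[c] = j
    has_rare = rare.size > 0
    if has_rare:
        column_of[rare] = len(common) - 1
    return column_of, int(common.size), has_rare, common


def association_arrays(
    F: np.ndarray,
    M1: np.ndarray,
    M2: np.ndarray,
    is_male: np.ndarray,
    column_of: np.ndarray,
    n_columns: int,
) -> np.ndarray:
    """Dosage tensor (n, 3, p) of the association risk sets, case at index 0,
    under "double" male coding. Noninformative families must be excluded
    beforehand."""
    n = F.shape[0]
    X = np.zeros((n, 3, n_columns))
    # alternative j carries haplotypes (altA[:, j], altB[:, j]); males carry
    # only altA with weight 2
    altA = np.where(is_male[:, None], np.stack([M1, M2, F], 1), np.stack([M1, M2, M1], 1))
    altB = np.stack([F, F, M2], 1)
    weight = np.where(is_male, 2.0, 1.0)
    rows = np.repeat(np.arange(n), 3)
    alts = np.tile(np.arange(3), n)
    colA = column_of[altA].ravel()
    ok = colA >= 0
    np.add.at(X, (rows[ok], alts[ok], colA[ok]), np.repeat(weight, 3)[ok])
    female_rows = ~is_male
    colB = column_of[altB].ravel()
    okB = (colB >= 0) & np.repeat(female_rows, 3)
    np.add.at(X, (rows[okB], alts[okB], colB[okB]), 1.0)
    return X


@dataclass(frozen=True)
class StudyResult:
    """Rejection-rate summary of a simulation study."""

    scenario: str
    n_datasets: int
    n_families: int
    alpha: float
    n_rejected: int
    n_failed: int
    rejection_rate: float
    rejection_se: float
    risk_beta_mean: float
    risk_beta_sd: float
    risk_betas: tuple[float, ...] = ()
    p_values: tuple[float, ...] = ()

    def summary_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_datasets": self.n_datasets,
            "n_families": self.n_families,
            "alpha": self.alpha,
            "n_rejected": self.n_rejected,
            "n_failed": self.n_failed,
            "rejection_rate": self.rejection_rate,
            "rejection_se": self.rejection_se,
            "risk_beta_mean": self.risk_beta_mean,
            "risk_beta_sd": self.risk_beta_sd,
        }


def analyze_dataset_codes(
    F: np.ndarray,
    M1: np.ndarray,
    M2: np.ndarray,
    is_male: np.ndarray,
    width: int,
    rare_threshold: float,
):
    """Run phasing + codebook + LRT on one simulated dataset (fast path).

    The dataset is first degraded to genotype matrices and re-phased, so
    the study exercises the same arithmetic as the file-based pipeline.
    Returns (LRTResult, common_codes).
    """
    bits = _code_bits(width)
    father_g = bits[F]
    mother_g = bits[M1] + bits[M2]
    child_g = np.where(is_male[:, None], bits[M1], bits[F] + bits[M1])
    fa, m1g, m2g, valid = phase_window_arrays(father_g, mother_g, child_g, is_male)
    if not valid.all():  # simulated complete triads always re-phase
        raise AssertionError("round-trip phasing failed on simulated data")
    powers = 2 ** np.arange(width - 1, -1, -1)
    Fc, M1c, M2c = fa @ powers, m1g @ powers, m2g @ powers
    informative = ~((Fc == M1c) & (M1c == M2c))
    Fc, M1c, M2c, male = Fc[informative], M1c[informative], M2c[informative], is_male[informative]
    parental = np.concatenate([Fc, M1c, M2c])
    column_of, n_common, has_rare, common = codebook_from_codes(parental, width, rare_threshold)
    p = n_common - 1 + (1 if has_rare else 0)
    X = association_arrays(Fc, M1c, M2c, male, column_of, p)
    mask = np.ones((X.shape[0], 3), dtype=bool)
    case_idx = np.zeros(X.shape[0], dtype=np.intp)
    null_cols = [p - 1] if has_rare else []
    result = lrt_arrays(X, mask, case_idx, null_cols, df=n_common - 1)
    return result, common, column_of


def run_study(
    scenario: ScenarioName,
    n_datasets: int,
    n_families: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    rare_threshold: float = 0.01,
    risk_frequency: float | None = None,
) -> StudyResult:
    """Simulate ``n_datasets`` studies and summarize the LRT rejection rate.

    Per-dataset random substreams are spawned from ``seed`` so results are
    reproducible and independent of execution order. For risk scenarios the
    fitted log-relative-risk of the primary risk haplotype is also
    collected (its column coefficient; exp(2 beta) estimates the boys'
    relative risk under "double" coding).
    """
    config = scenario_config(scenario, n_families=n_families, risk_frequency=risk_frequency)
    width = config.width
    risk_code = hap_to_code(RISK_HAPLOTYPE) if scenario in ("A", "B", "C") else None
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_datasets)
    n_rej = 0
    n_failed = 0
    betas: list[float] = []
    pvals: list[float] = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        F, M1, M2, male = draw_families(config, rng, n_families)
        result, common, column_of = analyze_dataset_codes(
            F, M1, M2, male, width, rare_threshold
        )
        if result.status == "nonconverged" or not np.isfinite(result.p_value):
            n_failed += 1
            continue
        pvals.append(result.p_value)
        if result.p_value < alpha:
            n_rej += 1
        if risk_code is not None and np.any(common[1:] == risk_code):
            # the risk haplotype has its own (non-reference, non-rare) column
            col = int(column_of[risk_code])
            betas.append(result.fit_alt.coefficients.get(col, 0.0))
    n_eff = n_datasets - n_failed
    rate = n_rej / n_eff if n_eff else float("nan")
    se = math.sqrt(rate * (1 - rate) / n_eff) if n_eff else float("nan")
    beta_arr = np.asarray(betas, dtype=float)
    return StudyResult(
        scenario=scenario,
        n_datasets=n_datasets,
        n_families=n_families,
        alpha=alpha,
        n_rejected=n_rej,
        n_failed=n_failed,
        rejection_rate=rate,
        rejection_se=se,
        risk_beta_mean=float(beta_arr.mean()) if len(betas) else float("nan"),
        risk_beta_sd=float(beta_arr.std(ddof=1)) if len(betas) > 1 else float("nan"),
        risk_betas=tuple(betas),
        p_values=tuple(pvals),
    )
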