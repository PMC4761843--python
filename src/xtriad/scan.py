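"""Sliding-window haplotype scan, diagnostics, and plot outputs.

The scan slides a fixed-width window (default 4 SNPs) along the filtered
X panel in map order. Within each window every complete triad is phased;
families with a missing call or Mendelian inconsistency are dropped for
that window only (window-local exclusion maximizes data use), the
rare-haplotype codebook is built from the remaining parental haplotypes,
and both the association LRT and the parental-exchangeability (PHE) LRT
are computed. With S SNPs passing the filter and width W there are
S - (W - 1) windows, and the Bonferroni family-wise threshold is
alpha / (number of windows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clr import Coding, LRTResult, SexSubset, build_codebook, lrt
from .errors import (
    DegenerateWindowError,
    EmptyPanelError,
    MendelianError,
    MissingGenotypeError,
    NoninformativeFamilyError,
)
from .phe import phe_lrt
from .pseudo import build_risk_set
from .triads import MISSING, PhasedTriad, TriadGenotypes, is_informative, phase_triad

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the sliding-window scan."""

    window_width: int = 4
    maf_threshold: float = 0.05  # parental MAF filter, strict inequality
    rare_threshold: float = 0.01  # haplotype pooling threshold
    alpha: float = 0.05  # family-wise error rate for Bonferroni
    coding: Coding = "double"
    sex_subset: SexSubset = "both"
    # keep single-parent families with an affected son, using the one
    # available pseudo-brother (off by default: the main method uses
    # complete triads only)
    allow_missing_parent_boys: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in (0, 0.5)")
        if not 0 <= self.rare_threshold < 1:
            raise ValueError("rare_threshold must be in [0, 1)")
        if self.window_width < 1:
            raise ValueError("window_width must be >= 1")


@dataclass(frozen=True)
class WindowResult:
    """Association and PHE tests of one window."""

    index: int
    first_snp_id: str
    first_snp_pos: int
    association: LRTResult | None
    phe: LRTResult | None
    n_informative: int
    n_excluded: int  # families dropped in this window (missing / Mendelian)
    bonferroni_threshold: float
    status: str  # "ok" or the reason the window could not be tested


@dataclass(frozen=True)
class ScanResult:
    windows: list[WindowResult]
    n_snps: int
    n_windows: int
    bonferroni_threshold: float
    config: ScanConfig


def parental_maf(triads: Sequence[TriadGenotypes]) -> np.ndarray:
    """Parental minor-allele frequency per locus: one X per father, two per
    mother; missing calls are ignored."""
    fathers = np.stack([t.father for t in triads])
    mothers = np.stack([t.mother for t in triads])
    f_called = fathers != MISSING
    m_called = mothers != MISSING
    copies = np.where(f_called, fathers, 0).sum(0) + np.where(m_called, mothers, 0).sum(0)
    denom = f_called.sum(0) + 2 * m_called.sum(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, copies / denom, 0.0)


def filter_snps(
    triads: Sequence[TriadGenotypes],
    snp_table: pd.DataFrame,
    maf_threshold: float = 0.05,
    exclude: Iterable[str] = (),
) -> tuple[list[TriadGenotypes], pd.DataFrame]:
    """Keep SNPs with parental MAF strictly above the threshold and not on
    the exclusion list, preserving map order. Raises
    :class:`EmptyPanelError` when nothing survives."""
    excluded = set(exclude)
    maf = parental_maf(triads)
    keep = (maf > maf_threshold) & ~snp_table["snp_id"].isin(excluded).to_numpy()
    if not keep.any():
        raise EmptyPanelError("no SNPs pass the MAF filter / exclusion list")
    idx = np.flatnonzero(keep)
    table = snp_table.iloc[idx].reset_index(drop=True).copy()
    table["maf"] = maf[idx]
    sliced = [
        TriadGenotypes(
            family_id=t.family_id,
            father=t.father[idx],
            mother=t.mother[idx],
            child=t.child[idx],
            child_sex=t.child_sex,
        )
        for t in triads
    ]
    logger.info("SNP filter: %d of %d SNPs retained", len(idx), len(snp_table))
    return sliced, table


def bonferroni_threshold(n_snps: int, window_width: int, alpha: float = 0.05) -> float:
    """alpha divided by the number of windows, S - (W - 1)."""
    n_windows = n_snps - (window_width - 1)
    if n_windows < 1:
        raise EmptyPanelError(f"{n_snps} SNPs cannot host a width-{window_width} window")
    return alpha / n_windows


def phase_window(
    triads: Sequence[TriadGenotypes], start: int, width: int
) -> tuple[list[PhasedTriad], int]:
    """Phase all families for one window; returns (phased, n_excluded)."""
    phased: list[PhasedTriad] = []
    excluded = 0
    for t in triads:
        try:
            phased.append(phase_triad(t.window(start, width)))
        except (MendelianError, MissingGenotypeError):
            excluded += 1
    return phased, excluded


def _is_dyad(t: TriadGenotypes) -> bool:
    return bool((t.father == MISSING).all() or (t.mother == MISSING).all())


def _dyad_risk_sets(dyads: Sequence[TriadGenotypes], start: int, width: int) -> list:
    """Two-alternative strata for single-parent families with affected sons.

    Dyads contribute conditional-logistic strata only; codebook frequencies
    come from complete triads, and the PHE test (which needs the father)
    skips them.
    """
    from .pseudo import build_single_pseudo_sib

    out = []
    for t in dyads:
        tw = t.window(start, width)
        if (tw.child == MISSING).any():
            continue
        try:
            if (tw.father == MISSING).all():
                if (tw.mother == MISSING).any():
                    continue
                rs = build_single_pseudo_sib(
                    tw.mother, tw.child, family_id=tw.family_id
                )
            else:
                if (tw.father == MISSING).any():
                    continue
                rs = build_single_pseudo_sib(
                    None, tw.child, father_haplotype=tw.father, family_id=tw.family_id
                )
        except (MendelianError, NoninformativeFamilyError, ValueError):
            continue
        out.append(rs)
    return out


def scan(
    triads: Sequence[TriadGenotypes],
    snp_table: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
) -> ScanResult:
    """Run the association + PHE scan over every window of the panel.

    Per-window degeneracies (too few common haplotypes, no informative
    families) are recorded in the window status and the scan continues.
    The Bonferroni denominator counts all windows attempted.
    """
    n_snps = len(snp_table)
    w = config.window_width
    threshold = bonferroni_threshold(n_snps, w, config.alpha)
    n_windows = n_snps - (w - 1)
    complete = [t for t in triads if not _is_dyad(t)]
    dyads = [t for t in triads if _is_dyad(t)] if config.allow_missing_parent_boys else []
    results: list[WindowResult] = []
    for i in range(n_windows):
        first = snp_table.iloc[i]
        window_id = f"win{i + 1}"
        phased, excluded = phase_window(complete, i, w)
        informative = [ph for ph in phased if is_informative(ph)]
        assoc = phe = None
        status = "ok"
        if not informative:
            status = "no informative families"
        else:
            try:
                codebook = build_codebook(
                    informative, config.rare_threshold, window_id=window_id
                )
                risk_sets = [build_risk_set(ph) for ph in informative]
                risk_sets += _dyad_risk_sets(dyads, i, w)
                assoc = lrt(risk_sets, codebook, config.coding, config.sex_subset)
                phe = phe_lrt(informative, codebook)
            except DegenerateWindowError as exc:
                status = f"degenerate: {exc}"
        results.append(
            WindowResult(
                index=i,
                first_snp_id=str(first["snp_id"]),
                first_snp_pos=int(first["pos"]),
                association=assoc,
                phe=phe,
                n_informative=len(informative),
                n_excluded=excluded,
                bonferroni_threshold=threshold,
                status=status,
            )
        )
    logger.info(
        "scan: %d SNPs, %d windows, Bonferroni threshold %.3g", n_snps, n_windows, threshold
    )
    return ScanResult(
        windows=results,
        n_snps=n_snps,
        n_windows=n_windows,
        bonferroni_threshold=threshold,
        config=config,
    )


def _coef_string(result: LRTResult | None) -> str:
    if result is None or result.fit_alt is None:
        return ""
    parts = []
    for label, beta in result.fit_alt.coefficients.items():
        name = label.to_string() if hasattr(label, "to_string") else str(label)
        parts.append(f"{name}={beta:.4f}({np.exp(beta):.3f})")
    return ";".join(parts)


def results_frame(result: ScanResult) -> pd.DataFrame:
    """Flatten a scan into the tab-separated results table."""
    rows = []
    for wr in result.windows:
        a, ph = wr.association, wr.phe
        rows.append(
            {
                "window_id": f"win{wr.index + 1}",
                "first_snp_id": wr.first_snp_id,
                "first_snp_pos": wr.first_snp_pos,
                "n_informative": wr.n_informative,
                "n_excluded": wr.n_excluded,
                "n_common": (a.df + 1) if a is not None else np.nan,
                "df": a.df if a is not None else np.nan,
                "chi2": a.chi2 if a is not None else np.nan,
                "p": a.p_value if a is not None else np.nan,
                "phe_chi2": ph.chi2 if ph is not None else np.nan,
                "phe_p": ph.p_value if ph is not None else np.nan,
                "bonferroni_threshold": wr.bonferroni_threshold,
                "status": wr.status,
                "coefficients": _coef_string(a),
            }
        )
    return pd.DataFrame(rows)


def write_results(result: ScanResult, path: str | Path) -> None:
    results_frame(result).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Informative-missingness diagnostic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrosstabResult:
    """Genotype-at-A by called/missing-at-B table for one family role."""

    role: str
    table: pd.DataFrame  # rows: genotype at locus_a (incl. NA); cols: called / missing
    carrier_table: np.ndarray  # 2x2 [carrier, noncarrier] x [missing, called]
    p_value: float
    flagged: bool


def _role_vectors(
    triads: Sequence[TriadGenotypes], locus_a: int, locus_b: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, list[tuple[int, int]]] = {
        "father": [], "mother": [], "son": [], "daughter": []
    }
    for t in triads:
        out["father"].append((t.father[locus_a], t.father[locus_b]))
        out["mother"].append((t.mother[locus_a], t.mother[locus_b]))
        child_role = "son" if t.child_sex == "male" else "daughter"
        out[child_role].append((t.child[locus_a], t.child[locus_b]))
    return {
        role: (np.array([a for a, _ in v]), np.array([b for _, b in v]))
        for role, v in out.items()
        if v
    }


def missingness_crosstab(
    triads: Sequence[TriadGenotypes],
    locus_a: int,
    locus_b: int,
    alpha: float = 0.05,
) -> dict[str, CrosstabResult]:
    """Cross-tabulate genotype at one locus against call failure at another.

    Genotype call failure at ``locus_b`` that depends on the genotype at
    ``locus_a`` ("informative missingness") can fabricate haplotype
    signals. For each family role, the full genotype x called/missing
    table is returned together with a two-sided Fisher exact test on the
    collapsed carrier-status x missingness margin (rows missing at
    ``locus_a`` are excluded from the 2x2). Roles with p below ``alpha``
    are flagged; a "pooled" entry aggregates all roles.
    """
    per_role = _role_vectors(triads, locus_a, locus_b)
    results: dict[str, CrosstabResult] = {}
    pooled = np.zeros((2, 2), dtype=int)
    for role, (ga, gb) in per_role.items():
        levels = [0, 1, 2, MISSING] if role in ("mother", "daughter") else [0, 1, MISSING]
        miss_b = gb == MISSING
        table = pd.DataFrame(
            {
                "called": [int(((ga == g) & ~miss_b).sum()) for g in levels],
                "missing": [int(((ga == g) & miss_b).sum()) for g in levels],
            },
            index=[("NA" if g == MISSING else str(g)) for g in levels],
        )
        called_a = ga != MISSING
        carrier = (ga > 0) & called_a
        two_by_two = np.array(
            [
                [int((carrier & miss_b).sum()), int((carrier & ~miss_b).sum())],
                [int((~carrier & called_a & miss_b).sum()),
                 int((~carrier & called_a & ~miss_b).sum())],
            ]
        )
        pooled += two_by_two
        _, p = stats.fisher_exact(two_by_two, alternative="two-sided")
        results[role] = CrosstabResult(role, table, two_by_two, float(p), p < alpha)
    _, p_pooled = stats.fisher_exact(pooled, alternative="two-sided")
    results["pooled"] = CrosstabResult(
        "pooled",
        pd.DataFrame(pooled, index=["carrier", "noncarrier"], columns=["missing", "called"]),
        pooled,
        float(p_pooled),
        p_pooled < alpha,
    )
    return results


# ---------------------------------------------------------------------------
# Plot outputs
# ---------------------------------------------------------------------------

def _neglog10(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return -np.log10(p)


def plot_tables(result: ScanResult) -> dict[str, pd.DataFrame]:
    """Plot-ready tables: Manhattan (position vs -log10 p) and QQ
    (expected vs observed -log10 p, expected quantiles -log10((i-0.5)/n))
    for both the association and PHE scans."""
    frame = results_frame(result)
    out: dict[str, pd.DataFrame] = {}
    for kind, col in (("association", "p"), ("phe", "phe_p")):
        sub = frame.loc[np.isfinite(frame[col]), ["first_snp_pos", col]]
        out[f"manhattan_{kind}"] = pd.DataFrame(
            {
                "pos": sub["first_snp_pos"].to_numpy(),
                "neglog10_p": _neglog10(sub[col].to_numpy()),
            }
        )
        p_sorted = np.sort(sub[col].to_numpy())
        n = len(p_sorted)
        expected = -np.log10((np.arange(1, n + 1) - 0.5) / n) if n else np.array([])
        # i-th smallest p pairs with expected quantile (i - 0.5) / n
        out[f"qq_{kind}"] = pd.DataFrame(
            {"expected": expected, "observed": _neglog10(p_sorted) if n else []}
        )
    return out


def plots(result: ScanResult, out_prefix: str | Path) -> list[Path]:
    """Write Manhattan/QQ data tables (TSV) and rendered PNG figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tables = plot_tables(result)
    written: list[Path] = []
    for name, frame in tables.items():
        path = prefix.with_name(f"{prefix.name}_{name}.tsv")
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    for kind in ("association", "phe"):
        man = tables[f"manhattan_{kind}"]
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.scatter(man["pos"], man["neglog10_p"], s=8, color="#1f4e79")
        ax.axhline(
            _neglog10(np.array([result.bonferroni_threshold]))[0],
            color="firebrick", linestyle="--", linewidth=1,
        )
        ax.set_xlabel("position of first SNP in window (bp)")
        ax.set_ylabel(r"$-\log_{10}(p)$")
        ax.set_title(f"{kind} scan")
        path = prefix.with_name(f"{prefix.name}_manhattan_{kind}.png")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

        qq = tables[f"qq_{kind}"]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(qq["expected"], qq["observed"], s=8, color="#1f4e79")
        lim = max(1.0, qq["expected"].max() if len(qq) else 1.0,
                  qq["observed"].max() if len(qq) else 1.0)
        ax.plot([0, lim], [0, lim], color="gray", linewidth=1)
        ax.set_xlabel(r"expected $-\log_{10}(p)$")
        ax.set_ylabel(r"observed $-\log_{10}(p)$")
        ax.set_title(f"{kind} QQ")
        path = prefix.with_name(f"{prefix.name}_qq_{kind}.png")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
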