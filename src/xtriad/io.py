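"""PED/MAP readers and writers for X-linked case-parent triads.

The interchange format is PLINK-style text pedigrees: a PED file with
columns FID, IID, PAT, MAT, SEX, PHENO followed by one allele pair per
SNP, and a MAP file with chromosome, SNP id, genetic distance and
physical position. Only X-chromosome maps are accepted. Affected children
are identified by PHENO = 2 and linked to their parents through the
PAT/MAT columns.

Male X genotypes appear in two dialects in the wild, both accepted here:
homozygous-coded allele pairs ("A A", the common convention) or a single
allele with the other slot set to the missing code "0" ("A 0"). A
genuinely heterozygous male X call raises :class:`SexCodeError`.

On load, alleles are normalized to minor-allele copy counts, where the
minor allele at each locus is the less frequent allele among parental X
chromosomes (one per father, two per mother); ties at 0.5 are broken
toward the lexicographically smaller allele label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, PedigreeError, SexCodeError
from .triads import MISSING, TriadGenotypes

_X_CHROM_CODES = {"x", "23", "chrx"}
MISSING_ALLELE = "0"


@dataclass
class _PedRecord:
    fid: str
    iid: str
    pat: str
    mat: str
    sex: str
    pheno: str
    alleles: list[tuple[str, str]]


def _parse_ped_line(line: str, lineno: int, n_snps: int) -> _PedRecord:
    fields = line.split()
    if len(fields) != 6 + 2 * n_snps:
        raise FormatError(
            f"PED line {lineno}: expected {6 + 2 * n_snps} fields "
            f"({n_snps} SNPs), got {len(fields)}"
        )
    pairs = [(fields[6 + 2 * i], fields[7 + 2 * i]) for i in range(n_snps)]
    return _PedRecord(*fields[:6], alleles=pairs)


def read_map(map_path: str | Path) -> pd.DataFrame:
    """Read a MAP file; rejects non-X chromosomes.

    Returns a frame with columns chrom, snp_id, cm, pos in file (panel)
    order; positions are 1-based physical coordinates.
    """
    rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(f"MAP line {lineno}: expected 4 columns, got {len(fields)}")
        chrom, snp_id, cm, pos = fields
        if chrom.lower() not in _X_CHROM_CODES:
            raise FormatError(f"MAP line {lineno}: chromosome {chrom!r} is not the X")
        rows.append((chrom, snp_id, float(cm), int(pos)))
    if not rows:
        raise FormatError(f"{map_path}: empty MAP file")
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "pos"])


def _hemizygous_count(pair: tuple[str, str], minor: str | None, who: str) -> int:
    """Copy count for a male X call; accepts homozygous or single-allele coding."""
    a, b = pair
    present = [x for x in (a, b) if x != MISSING_ALLELE]
    if not present:
        return MISSING
    if len(present) == 2 and a != b:
        raise SexCodeError(f"{who}: heterozygous X call {a}/{b} in a male")
    return int(present[0] == minor)


def _diploid_count(pair: tuple[str, str], minor: str | None) -> int:
    a, b = pair
    if MISSING_ALLELE in (a, b):
        return MISSING
    return int(a == minor) + int(b == minor)


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    allow_missing_parent_boys: bool = False,
) -> tuple[list[TriadGenotypes], pd.DataFrame]:
    """Load complete case-parent triads and the SNP panel.

    Returns the triads (genotypes as minor-allele copy counts, ``MISSING``
    for failed calls) and the SNP table augmented with the minor/major
    allele labels and the parental minor-allele frequency ``maf``. Families
    whose affected child cannot be linked to a genotyped father and mother
    raise :class:`PedigreeError`; with several affected children the first
    is used. With ``allow_missing_parent_boys`` (off by default, as the main
    method requires complete triads), single-parent families with an
    affected son are kept, the absent parent coded all-missing.
    """
    snps = read_map(map_path)
    n_snps = len(snps)
    records: list[_PedRecord] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if line.strip():
            records.append(_parse_ped_line(line, lineno, n_snps))
    by_key = {(r.fid, r.iid): r for r in records}

    trios: list[tuple[_PedRecord, _PedRecord, _PedRecord]] = []  # father, mother, child
    seen_fids = set()
    for r in records:
        if r.pheno != "2" or r.pat == "0" or r.mat == "0":
            continue
        if r.fid in seen_fids:  # multiplex family: keep the first affected child
            continue
        father = by_key.get((r.fid, r.pat))
        mother = by_key.get((r.fid, r.mat))
        if father is None or mother is None:
            # optional mother-son / father-son dyads: the absent parent is
            # synthesized as all-missing and handled by the single
            # pseudo-brother construction downstream
            one_parent = (father is None) != (mother is None)
            if allow_missing_parent_boys and r.sex == "1" and one_parent:
                blank = [(MISSING_ALLELE, MISSING_ALLELE)] * n_snps
                if father is None:
                    father = _PedRecord(r.fid, r.pat, "0", "0", "1", "1", blank)
                else:
                    mother = _PedRecord(r.fid, r.mat, "0", "0", "2", "1", blank)
            else:
                raise PedigreeError(
                    f"family {r.fid}: affected child {r.iid} has ungenotyped parent(s)"
                )
        if r.sex not in ("1", "2"):
            raise PedigreeError(f"family {r.fid}: child {r.iid} has sex code {r.sex!r}")
        trios.append((father, mother, r))
        seen_fids.add(r.fid)
    if not trios:
        raise PedigreeError(f"{ped_path}: no complete triads with an affected child")

    # minor allele per locus from parental X chromosomes (1 per father, 2 per mother)
    minor: list[str | None] = []
    major: list[str | None] = []
    mafs: list[float] = []
    for j in range(n_snps):
        counts: dict[str, float] = {}
        for father, mother, _child in trios:
            fa, fb = father.alleles[j]
            f_alleles = [x for x in (fa, fb) if x != MISSING_ALLELE]
            if f_alleles:
                if len(f_alleles) == 2 and f_alleles[0] != f_alleles[1]:
                    raise SexCodeError(
                        f"father {father.iid}: heterozygous X call at SNP "
                        f"{snps.snp_id[j]}"
                    )
                counts[f_alleles[0]] = counts.get(f_alleles[0], 0) + 1
            ma, mb = mother.alleles[j]
            if MISSING_ALLELE not in (ma, mb):
                for x in (ma, mb):
                    counts[x] = counts.get(x, 0) + 1
        if len(counts) > 2:
            raise FormatError(f"SNP {snps.snp_id[j]}: more than two alleles {sorted(counts)}")
        if not counts:
            minor.append(None)
            major.append(None)
            mafs.append(0.0)
            continue
        alleles = sorted(counts, key=lambda a: (counts[a], a))  # ascending frequency
        total = sum(counts.values())
        if len(alleles) == 1:
            minor.append(None)  # monomorphic: every count is 0
            major.append(alleles[0])
            mafs.append(0.0)
        else:
            minor.append(alleles[0])
            major.append(alleles[1])
            mafs.append(counts[alleles[0]] / total)

    triads = []
    for father, mother, child in trios:
        f = np.array(
            [_hemizygous_count(father.alleles[j], minor[j], f"father {father.iid}")
             for j in range(n_snps)],
            dtype=np.int8,
        )
        m = np.array(
            [_diploid_count(mother.alleles[j], minor[j]) for j in range(n_snps)],
            dtype=np.int8,
        )
        if child.sex == "1":
            c = np.array(
                [_hemizygous_count(child.alleles[j], minor[j], f"son {child.iid}")
                 for j in range(n_snps)],
                dtype=np.int8,
            )
            sex = "male"
        else:
            c = np.array(
                [_diploid_count(child.alleles[j], minor[j]) for j in range(n_snps)],
                dtype=np.int8,
            )
            sex = "female"
        triads.append(
            TriadGenotypes(family_id=child.fid, father=f, mother=m, child=c, child_sex=sex)
        )

    table = snps.copy()
    table["minor"] = minor
    table["major"] = major
    table["maf"] = mafs
    return triads, table


#: Allele labels used when writing simulated data (minor, major).
_WRITE_ALLELES = ("A", "G")


def write_ped_map(
    triads: Sequence[TriadGenotypes],
    ped_path: str | Path,
    map_path: str | Path,
    snp_table: pd.DataFrame | None = None,
) -> None:
    """Write triads as PED/MAP text, males homozygous-coded.

    Minor-allele count 1 (males) or {0,1,2} (females) maps to allele pairs
    over ('A' = minor, 'G' = major); missing calls become "0 0". Without a
    SNP table, ids snp1..snpL at 1-based positions 1kb apart are invented.
    """
    n_snps = triads[0].n_loci if triads else 0
    if snp_table is None:
        snp_table = pd.DataFrame(
            {
                "chrom": ["X"] * n_snps,
                "snp_id": [f"snp{j + 1}" for j in range(n_snps)],
                "cm": [0.0] * n_snps,
                "pos": [1 + 1000 * j for j in range(n_snps)],
            }
        )
    with open(map_path, "w") as fh:
        for row in snp_table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t{row.cm:g}\t{row.pos}\n")

    minor, major = _WRITE_ALLELES

    def pair(count: int, hemizygous: bool) -> str:
        if count == MISSING:
            return "0 0"
        if hemizygous:
            allele = minor if count == 1 else major
            return f"{allele} {allele}"
        return " ".join([minor] * count + [major] * (2 - count))

    with open(ped_path, "w") as fh:
        for t in triads:
            fid = t.family_id
            father_id, mother_id, child_id = f"{fid}_f", f"{fid}_m", f"{fid}_c"
            child_sexcode = "1" if t.child_sex == "male" else "2"
            rows = [
                (father_id, "0", "0", "1", "1", t.father, True),
                (mother_id, "0", "0", "2", "1", t.mother, False),
                (child_id, father_id, mother_id, child_sexcode, "2",
                 t.child, t.child_sex == "male"),
            ]
            for iid, pat, mat, sexcode, pheno, geno, hemi in rows:
                gt = " ".join(pair(int(g), hemi) for g in geno)
                fh.write(f"{fid} {iid} {pat} {mat} {sexcode} {pheno} {gt}\n")
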