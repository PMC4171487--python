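"""Nuclear-family cohorts: reading pedigree + genotype data, allele
frequencies from parents, and common/rare variant classification.

A :class:`Cohort` stores genotypes as minor-allele dosages (0/1/2, -1 for
missing) in dense per-role arrays: ``fathers`` and ``mothers`` are
``(F, V)`` matrices and children live in a padded ``(F, K, V)`` array with
a presence mask.  The minor allele at every site is defined from the
*parental* genotypes only; sites are recoded at load time so dosage counts
the minor allele.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VariantRecord",
    "NuclearFamily",
    "Cohort",
    "RegionMap",
    "read_cohort",
    "read_vcf",
    "read_ped",
    "read_region_file",
    "estimate_maf",
    "classify_variants",
    "DEFAULT_THRESHOLDS",
    "COMMON_CUT",
]

#: MAF thresholds for the variable-threshold rare-variant statistic.
DEFAULT_THRESHOLDS = (0.05, 0.03, 0.01, 0.005)
#: Variants with parental MAF strictly above this are "common" for analysis.
COMMON_CUT = 0.05

MISSING = -1


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic site; ``maf`` is estimated from parental genotypes."""

    id: str
    chrom: str
    pos: int  # 1-based
    minor_allele: str
    major_allele: str
    maf: float


@dataclass
class NuclearFamily:
    """Two parents and >=1 child; genotypes are minor-allele dosages."""

    family_id: str
    father_genotypes: np.ndarray
    mother_genotypes: np.ndarray
    children: list[tuple[np.ndarray, bool]] = field(default_factory=list)

    @property
    def n_children(self) -> int:
        return len(self.children)


class Cohort:
    """All families share one ordered variant list.

    Parameters
    ----------
    fathers, mothers:
        ``(F, V)`` int8 dosage matrices, -1 for missing.
    children:
        ``(F, K, V)`` int8, -1 for missing genotype or absent child slot.
    child_present:
        ``(F, K)`` bool mask of real children.
    affected:
        ``(F, K)`` bool affection status (False where no child).
    """

    def __init__(
        self,
        family_ids: list[str],
        variants: list[VariantRecord],
        fathers: np.ndarray,
        mothers: np.ndarray,
        children: np.ndarray,
        child_present: np.ndarray,
        affected: np.ndarray,
    ):
        self.family_ids = list(family_ids)
        self.variants = list(variants)
        self.fathers = np.asarray(fathers, dtype=np.int8)
        self.mothers = np.asarray(mothers, dtype=np.int8)
        self.children = np.asarray(children, dtype=np.int8)
        self.child_present = np.asarray(child_present, dtype=bool)
        self.affected = np.asarray(affected, dtype=bool) & self.child_present
        F, V = self.fathers.shape
        if self.children.ndim == 2:  # single child slot
            self.children = self.children[:, None, :]
        assert self.children.shape[0] == F and self.children.shape[2] == V
        assert self.child_present.shape == self.children.shape[:2]
        if not self.child_present.any(axis=1).all():
            raise ValueError("every family must have at least one child")

    # -- basic views ---------------------------------------------------
    @property
    def n_families(self) -> int:
        return self.fathers.shape[0]

    @property
    def n_variants(self) -> int:
        return self.fathers.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return np.array([v.maf for v in self.variants])

    @property
    def chrom(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def pos(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    def family(self, i: int) -> NuclearFamily:
        kids = [
            (self.children[i, k].copy(), bool(self.affected[i, k]))
            for k in range(self.children.shape[1])
            if self.child_present[i, k]
        ]
        return NuclearFamily(
            self.family_ids[i], self.fathers[i].copy(), self.mothers[i].copy(), kids
        )

    @classmethod
    def from_families(
        cls, families: list[NuclearFamily], variants: list[VariantRecord]
    ) -> "Cohort":
        F = len(families)
        V = len(variants)
        K = max(f.n_children for f in families)
        fathers = np.full((F, V), MISSING, np.int8)
        mothers = np.full((F, V), MISSING, np.int8)
        children = np.full((F, K, V), MISSING, np.int8)
        present = np.zeros((F, K), bool)
        affected = np.zeros((F, K), bool)
        for i, fam in enumerate(families):
            fathers[i] = fam.father_genotypes
            mothers[i] = fam.mother_genotypes
            for k, (g, aff) in enumerate(fam.children):
                children[i, k] = g
                present[i, k] = True
                affected[i, k] = aff
        return cls([f.family_id for f in families], variants, fathers, mothers,
                   children, present, affected)


# ---------------------------------------------------------------------------
# allele frequencies and variant classification
# ---------------------------------------------------------------------------

def estimate_maf(fathers: np.ndarray, mothers: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per site from parental genotypes only.

    Each parent contributes two alleles; missing parents are dropped from
    both numerator and denominator.  Returns NaN where no parent is typed.
    """
    parents = np.concatenate([fathers, mothers], axis=0).astype(np.int64)
    ok = parents >= 0
    n_alleles = 2 * ok.sum(axis=0)
    count = np.where(ok, parents, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, count / np.maximum(n_alleles, 1), np.nan)
    return freq


def classify_variants(
    maf: np.ndarray,
    common_cut: float = COMMON_CUT,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Partition variant indices into the common set (MAF > cut) and one
    rare set per threshold t (MAF < t).  Strict inequalities: a variant with
    MAF exactly at the cut belongs to neither set.
    """
    maf = np.asarray(maf, float)
    common = np.flatnonzero(maf > common_cut)
    rare = {t: np.flatnonzero(maf < t) for t in thresholds}
    return common, rare


def mendelian_ok(fathers: np.ndarray, mothers: np.ndarray, child: np.ndarray) -> np.ndarray:
    """Elementwise Mendelian consistency of dosages (True where any member
    is missing: consistency is only checkable on complete triples)."""
    f, m, c = fathers, mothers, child
    complete = (f >= 0) & (m >= 0) & (c >= 0)
    cmin = (f == 2).astype(np.int8) + (m == 2).astype(np.int8)
    cmax = (f >= 1).astype(np.int8) + (m >= 1).astype(np.int8)
    ok = (c >= cmin) & (c <= cmax)
    return ok | ~complete


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    pass


def _finalize_cohort(
    family_ids, fathers, mothers, children, present, affected, chroms, poss, ids,
    ref_alleles, alt_alleles,
) -> Cohort:
    """Recode to minor-allele dosage, drop monomorphic sites, build records."""
    fathers = np.asarray(fathers, np.int8)
    mothers = np.asarray(mothers, np.int8)
    children = np.asarray(children, np.int8)
    freq = estimate_maf(fathers, mothers)  # frequency of allele coded as dosage
    keep = []
    variants = []
    for j in range(fathers.shape[1]):
        q = freq[j]
        if not np.isfinite(q):
            continue
        if q > 0.5:
            for arr in (fathers, mothers):
                col = arr[:, j]
                col[col >= 0] = 2 - col[col >= 0]
            col = children[:, :, j]
            col[col >= 0] = 2 - col[col >= 0]
            q = 1.0 - q
            minor, major = ref_alleles[j], alt_alleles[j]
        else:
            minor, major = alt_alleles[j], ref_alleles[j]
        if q <= 0.0:
            continue  # monomorphic in parents
        keep.append(j)
        variants.append(VariantRecord(ids[j], str(chroms[j]), int(poss[j]), minor, major, float(q)))
    keep = np.array(keep, int)
    return Cohort(
        family_ids,
        variants,
        fathers[:, keep],
        mothers[:, keep],
        children[:, :, keep],
        present,
        affected,
    )


def _read_fam(path: str) -> list[tuple[str, str, str, str, bool]]:
    """6-column FAM/PED pedigree: fid iid father mother sex phenotype.
    Phenotype coding 2=affected, 1=unaffected, 0/-9=unknown."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln}: expected >=6 columns")
            fid, iid, fa, mo, _sex, pheno = parts[:6]
            rows.append((fid, iid, fa, mo, pheno == "2"))
    return rows


def _assemble(ped_rows, geno_by_iid, chroms, poss, ids, refs, alts) -> Cohort:
    """Group pedigree rows into nuclear families keyed by (fid, father, mother)."""
    iids = {iid for _, iid, *_ in ped_rows}
    fam_children: dict[tuple[str, str, str], list[tuple[str, bool]]] = {}
    for fid, iid, fa, mo, aff in ped_rows:
        if fa in ("0", "") or mo in ("0", ""):
            continue  # founder row
        if fa not in iids or mo not in iids:
            continue
        fam_children.setdefault((fid, fa, mo), []).append((iid, aff))
    if not fam_children:
        raise ParseError("pedigree contains no child with two declared parents")
    V = len(ids)
    missing_row = np.full(V, MISSING, np.int8)
    family_ids, fat, mot, kids_list, aff_list = [], [], [], [], []
    # pedigree-file order (dict preserves first-appearance order)
    for (fid, fa, mo), kids in fam_children.items():
        family_ids.append(fid)
        fat.append(geno_by_iid.get(fa, missing_row))
        mot.append(geno_by_iid.get(mo, missing_row))
        kids_list.append([geno_by_iid.get(iid, missing_row) for iid, _ in kids])
        aff_list.append([a for _, a in kids])
    K = max(len(k) for k in kids_list)
    F = len(family_ids)
    children = np.full((F, K, V), MISSING, np.int8)
    present = np.zeros((F, K), bool)
    affected = np.zeros((F, K), bool)
    fathers = np.stack(fat)
    mothers = np.stack(mot)
    for i, (kids, affs) in enumerate(zip(kids_list, aff_list)):
        for k, g in enumerate(kids):
            children[i, k] = g
            present[i, k] = True
            affected[i, k] = affs[k]
    return _finalize_cohort(
        family_ids, fathers, mothers, children, present, affected,
        chroms, poss, ids, refs, alts,
    )


def read_vcf(vcf_path: str, fam_path: str) -> Cohort:
    """Read a VCF (biallelic SNVs; multi-allelic sites skipped) plus a
    6-column FAM pedigree into a :class:`Cohort`."""
    from cyvcf2 import VCF

    ped_rows = _read_fam(fam_path)
    vcf = VCF(vcf_path, gts012=True)
    samples = list(vcf.samples)
    chroms, poss, ids, refs, alts, cols = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        g = np.asarray(var.gt_types, np.int8)  # 0,1,2; 3=missing under gts012
        g = np.where(g == 3, MISSING, g)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0])
        cols.append(g)
    if not cols:
        raise ParseError(f"{vcf_path}: no biallelic variants found")
    G = np.stack(cols, axis=1)  # samples x variants, ALT dosage
    geno_by_iid = {iid: G[i] for i, iid in enumerate(samples)}
    return _assemble(ped_rows, geno_by_iid, chroms, poss, ids, refs, alts)


_ALLELE_RE = re.compile(r"^[0-9A-Za-z]$")


def read_ped(ped_path: str, map_path: str) -> Cohort:
    """Read linkage-format PED (two allele columns per site) + MAP."""
    chroms, ids, poss = [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 columns")
            chroms.append(parts[0])
            ids.append(parts[1])
            poss.append(int(parts[3]))
    V = len(ids)
    ped_rows = []
    allele_pairs: dict[str, list[tuple[str, str]]] = {}
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * V:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * V} columns, got {len(parts)}"
                )
            fid, iid, fa, mo, _sex, pheno = parts[:6]
            ped_rows.append((fid, iid, fa, mo, pheno == "2"))
            allele_pairs[iid] = [
                (parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(V)
            ]
    # allele labels per site (first seen = provisional ref)
    refs, alts = [], []
    geno_by_iid = {iid: np.full(V, MISSING, np.int8) for iid in allele_pairs}
    for j in range(V):
        labels: list[str] = []
        for iid, pairs in allele_pairs.items():
            for a in pairs[j]:
                if a != "0" and a not in labels:
                    labels.append(a)
        if len(labels) > 2:
            labels = []  # multi-allelic: leave all missing, dropped later
        labels_sorted = sorted(labels)
        ref = labels_sorted[0] if labels_sorted else "A"
        alt = labels_sorted[1] if len(labels_sorted) > 1 else "N"
        refs.append(ref)
        alts.append(alt)
        if not labels:
            continue
        for iid, pairs in allele_pairs.items():
            a, b = pairs[j]
            if a == "0" or b == "0":
                continue
            geno_by_iid[iid][j] = (a == alt) + (b == alt)
    return _assemble(ped_rows, geno_by_iid, chroms, poss, ids, refs, alts)


def read_cohort(
    genotypes: str, pedigree: str | None = None, map_file: str | None = None
) -> Cohort:
    """Dispatch on file type: VCF (+FAM) or linkage PED (+MAP)."""
    if genotypes.endswith((".vcf", ".vcf.gz")):
        if pedigree is None:
            raise ValueError("a FAM/PED pedigree file is required with a VCF")
        return read_vcf(genotypes, pedigree)
    if map_file is None:
        raise ValueError("a MAP file is required with a linkage PED")
    return read_ped(genotypes, map_file)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

class RegionMap(dict):
    """region name -> np.ndarray of variant indices into the cohort."""


_INTERVAL_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def read_region_file(path: str, cohort: Cohort) -> RegionMap:
    """Parse a set-ID file: ``region<TAB>variant_id`` lines (one pair per
    line) or ``region<TAB>chrom:start-end`` intervals (1-based inclusive)."""
    id_index = {v.id: j for j, v in enumerate(cohort.variants)}
    chrom = cohort.chrom
    pos = cohort.pos
    raw: dict[str, list[int]] = {}
    unknown: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 'region<TAB>id-or-interval'")
            region, token = parts
            m = _INTERVAL_RE.match(token)
            if m:
                sel = np.flatnonzero(
                    (chrom == m["chrom"])
                    & (pos >= int(m["start"]))
                    & (pos <= int(m["end"]))
                )
                raw.setdefault(region, []).extend(sel.tolist())
            elif token in id_index:
                raw.setdefault(region, []).append(id_index[token])
            else:
                unknown.setdefault(region, []).append(token)
                raw.setdefault(region, [])
    out = RegionMap()
    for region, idx in raw.items():
        seen: list[int] = []
        for j in idx:
            if j not in seen:
                seen.append(j)
        out[region] = np.array(seen, int)
    out.unknown_ids = unknown  # type: ignore[attr-defined]
    return out
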