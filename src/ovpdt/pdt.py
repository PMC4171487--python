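"""The Pedigree Disequilibrium Test statistic.

For a triad (two genotyped parents, one affected child) the transmission
score is T = (minor alleles transmitted) - (minor alleles not transmitted),
which for complete dosages reduces to ``T = 2*child - father - mother``
(each parent transmits one allele; the other is not transmitted).  For a
discordant sib pair, S = dosage(affected) - dosage(unaffected).  The family
score D_i averages T and S over the family's informative units, and the
single-variant statistic is

    X = (sum_i D_i)^2 / sum_i D_i^2  ~  chi-square(1 df) under the null.

Swapping transmitted and non-transmitted alleles in a family negates every
T and S in it, hence negates D_i; the permutation engine exploits this via
per-family sign flips (only the numerator of X changes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .families import Cohort, mendelian_ok

__all__ = [
    "triad_score",
    "sibpair_score",
    "family_score",
    "family_score_matrix",
    "pdt_statistic",
    "apply_sign_flips",
    "FamilyScoreMatrix",
]


def triad_score(father_g: int, mother_g: int, child_g: int) -> int:
    """Transmitted-minus-nontransmitted minor-allele count for one triad.

    Phase never matters: the two transmitted alleles sum to the child's
    dosage and the two non-transmitted alleles to (father+mother-child).
    """
    return 2 * int(child_g) - int(father_g) - int(mother_g)


def sibpair_score(affected_g: int, unaffected_g: int) -> int:
    return int(affected_g) - int(unaffected_g)


@dataclass
class FamilyScoreMatrix:
    """Per-family per-variant PDT scores and informative-unit counts."""

    D: np.ndarray      # (F, V) float64
    n_T: np.ndarray    # (F, V) int16: informative triads
    n_S: np.ndarray    # (F, V) int16: discordant sib pairs in informative sibships
    n_mendel_errors: int = 0

    @property
    def denominators(self) -> np.ndarray:
        return (self.D ** 2).sum(axis=0)


def family_score_matrix(cohort: Cohort) -> FamilyScoreMatrix:
    """Vectorized D_i over all families and variants.

    Per site and family: a triad is informative iff both parents and the
    affected child are typed, Mendelian-consistent, and >=1 parent is
    heterozygous.  A sibship contributes its affected x unaffected cross
    pairs iff at least one such pair differs at the site.  A Mendelian
    violation by any child zeroes the whole site for that family.
    """
    f = cohort.fathers.astype(np.int16)
    m = cohort.mothers.astype(np.int16)
    kids = cohort.children.astype(np.int16)  # (F, K, V)
    present = cohort.child_present
    affected = cohort.affected
    F, K, V = kids.shape

    parents_ok = (f >= 0) & (m >= 0)
    par_het = (f == 1) | (m == 1)

    sum_T = np.zeros((F, V), np.int32)
    n_T = np.zeros((F, V), np.int16)
    mendel_bad = np.zeros((F, V), bool)
    for k in range(K):
        c = kids[:, k, :]
        here = present[:, k][:, None] & (c >= 0)
        ok = mendelian_ok(f, m, c)
        mendel_bad |= here & ~ok
        tri = here & ok & parents_ok & affected[:, k][:, None] & par_het
        sum_T += np.where(tri, 2 * c - f - m, 0)
        n_T += tri

    sum_S = np.zeros((F, V), np.int32)
    n_pairs = np.zeros((F, V), np.int16)
    any_diff = np.zeros((F, V), bool)
    for a in range(K):
        for u in range(K):
            if a == u:
                continue
            pair_mask = (affected[:, a] & present[:, u] & ~affected[:, u])[:, None]
            ca = kids[:, a, :]
            cu = kids[:, u, :]
            ok = pair_mask & (ca >= 0) & (cu >= 0)
            s = ca - cu
            sum_S += np.where(ok, s, 0)
            n_pairs += ok
            any_diff |= ok & (s != 0)
    n_S = np.where(any_diff, n_pairs, 0).astype(np.int16)
    # non-informative sibships contribute nothing (their S sum is 0 anyway)

    denom = n_T.astype(np.int32) + n_S
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(denom > 0, (sum_T + sum_S) / np.maximum(denom, 1), 0.0)
    D[mendel_bad] = 0.0
    n_T = np.where(mendel_bad, 0, n_T).astype(np.int16)
    n_S = np.where(mendel_bad, 0, n_S).astype(np.int16)
    return FamilyScoreMatrix(D, n_T, n_S, int(mendel_bad.sum()))


def family_score(family, variant_index: int | None = None):
    """D_i for a single :class:`~ovpdt.families.NuclearFamily` (all sites,
    or one site if ``variant_index`` given).  Convenience wrapper over the
    vectorized path."""
    from .families import Cohort, VariantRecord

    V = len(family.father_genotypes)
    variants = [VariantRecord(str(j), "0", j + 1, "1", "2", 0.25) for j in range(V)]
    mat = family_score_matrix(Cohort.from_families([family], variants))
    d = mat.D[0]
    return d if variant_index is None else float(d[variant_index])


def pdt_statistic(D: np.ndarray) -> np.ndarray | float:
    """X = (sum D_i)^2 / (sum D_i^2), 0 where all D_i are 0."""
    D = np.asarray(D, float)
    one_d = D.ndim == 1
    if one_d:
        D = D[:, None]
    num = D.sum(axis=0) ** 2
    den = (D ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return float(X[0]) if one_d else X


def apply_sign_flips(
    score_matrix: FamilyScoreMatrix | np.ndarray, signs: np.ndarray
) -> np.ndarray:
    """Per-variant X after flipping each family's D_i by ``signs``.

    ``signs`` is ``(F,)`` or ``(B, F)`` of +/-1 (one sign per family,
    applied to every variant; the caller splits by chromosome when a region
    spans several).  Only the numerator changes: denominators are
    sign-invariant.
    """
    D = score_matrix.D if isinstance(score_matrix, FamilyScoreMatrix) else np.asarray(score_matrix, float)
    signs = np.asarray(signs, float)
    den = (D ** 2).sum(axis=0)
    num = (signs @ D) ** 2  # (V,) or (B, V)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
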