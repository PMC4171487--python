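"""The OVPDT region statistic and its adaptive sign-flip permutation test.

Pipeline per region:

1. normalised lr for common variants (MAF > 0.05), from parental mating
   types only;
2. single-variant PDT statistics X for all variants;
3. ordered-subset common statistic C: scan prefix sums of X in decreasing
   |lr| order, take the prefix with the smallest chi-square tail p-value,
   C = that prefix sum if min_p <= 0.05 else 0;
4. variable-threshold rare statistics R_t = sum of X over {MAF < t} for
   t in {0.05, 0.03, 0.01, 0.005}; combined M_t = R_t + C;
5. permute transmissions by one +/-1 sign per family (per chromosome,
   preserving LD and sibling IBD), recompute C and R_t with the *fixed*
   lr ordering;
6. standardise each M_t by the permutation mean/SD, M = max over t;
7. p = (#{permuted M_i > M} + 1) / (K + 1), with adaptive stopping once
   36 exceedances have accrued and K >= 2000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .families import COMMON_CUT, DEFAULT_THRESHOLDS, classify_variants
from .grr import lr_scores
from .pdt import FamilyScoreMatrix, family_score_matrix

__all__ = [
    "OrderedSubsetResult",
    "OVPDTResult",
    "PermutationConfig",
    "subset_order",
    "ordered_subset_statistic",
    "rare_statistic",
    "combined_statistic",
    "permutation_null",
    "standardize_and_maximize",
    "ovpdt_test",
    "permutation_pvalue",
]


@dataclass
class OrderedSubsetResult:
    order: np.ndarray          # common-variant indices, |lr| descending
    cumulative: np.ndarray     # prefix sums S_i of ordered X
    p_values: np.ndarray       # chi2 tail p at (S_i, i df)
    min_p: float
    C: float


@dataclass
class PermutationConfig:
    min_K: int = 2000
    target_exceedances: int = 36
    max_K: int = 1_000_000
    batch_size: int = 1000
    seed: int | np.random.SeedSequence = 0
    grr_bootstrap: int = 1000

    def __post_init__(self):
        if self.min_K < 1 or self.target_exceedances < 1:
            raise ValueError("min_K and target_exceedances must be >= 1")


@dataclass
class OVPDTResult:
    region: str
    n_common: int
    n_rare: dict[float, int]
    C: float
    min_p: float
    subset_size: int
    R: dict[float, float]
    M_t: dict[float, float]
    standardized: dict[float, float]
    chosen_t: float | None
    M: float
    K: int
    exceedances: int
    p_value: float
    testable: bool = True
    lr: np.ndarray | None = field(default=None, repr=False)


def subset_order(lr: np.ndarray, X: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Sort order for the ordered-subset scan: |lr| descending; ties by
    larger X, then position; lr == 0 variants after all others (same
    internal tie-break)."""
    lr = np.asarray(lr, float)
    X = np.asarray(X, float)
    pos = np.asarray(pos)
    zero_block = (lr == 0.0).astype(int)
    return np.lexsort((pos, -X, -np.abs(lr), zero_block))


def ordered_subset_statistic(
    X_common: np.ndarray,
    lr: np.ndarray,
    pos: np.ndarray | None = None,
    alpha_gate: float = 0.05,
) -> OrderedSubsetResult:
    """Eq-(4)-style scan: p_i = P(chi2_i >= S_i) treating the i ordered
    variants as independent; C is the prefix sum at the minimum p if that
    minimum is <= ``alpha_gate``, else 0."""
    X_common = np.asarray(X_common, float)
    n = X_common.size
    if n == 0:
        return OrderedSubsetResult(np.array([], int), np.array([]), np.array([]), 1.0, 0.0)
    if pos is None:
        pos = np.arange(n)
    order = subset_order(lr, X_common, pos)
    S = np.cumsum(X_common[order])
    dfs = np.arange(1, n + 1)
    p = chi2.sf(S, dfs)
    imin = int(p.argmin())
    min_p = float(p[imin])
    C = float(S[imin]) if min_p <= alpha_gate else 0.0
    return OrderedSubsetResult(order, S, p, min_p, C)


def rare_statistic(X_rare: np.ndarray) -> float:
    """Sum of single-variant PDT statistics over a rare set."""
    return float(np.asarray(X_rare, float).sum())


def combined_statistic(R_t: float, C: float) -> float:
    """Equal-weight combination M_t = R_t + C."""
    return R_t + C


def permutation_pvalue(exceedances: int, K: int) -> float:
    return (exceedances + 1) / (K + 1)


def _perm_C(
    X_perm: np.ndarray, order: np.ndarray, alpha_gate: float = 0.05
) -> np.ndarray:
    """Ordered-subset C for a (B, n_common) batch of permuted X, with the
    observed (fixed) ordering."""
    B, n = X_perm.shape
    if n == 0:
        return np.zeros(B)
    S = np.cumsum(X_perm[:, order], axis=1)
    p = chi2.sf(S, np.arange(1, n + 1)[None, :])
    imin = p.argmin(axis=1)
    rows = np.arange(B)
    return np.where(p[rows, imin] <= alpha_gate, S[rows, imin], 0.0)


def _batch_stats(
    D: np.ndarray,
    signs: np.ndarray,
    chrom_groups: list[np.ndarray],
    common_cols: np.ndarray,
    order: np.ndarray,
    rare_indicator: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(C, R) for a batch of sign assignments.

    ``signs`` is (B, F, n_chrom_groups); each group's variants share the
    family sign, so LD within a chromosome survives every permutation.
    """
    B = signs.shape[0]
    V = D.shape[1]
    den = (D ** 2).sum(axis=0)
    num = np.empty((B, V), np.float32)
    for g, cols in enumerate(chrom_groups):
        num[:, cols] = signs[:, :, g] @ D[:, cols].astype(np.float32)
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(den > 0, num.astype(np.float64) ** 2 / np.maximum(den, 1e-300), 0.0)
    C = _perm_C(X[:, common_cols], order)
    R = X @ rare_indicator  # (B, n_thresholds)
    return C, R


def permutation_null(
    score_matrix: FamilyScoreMatrix,
    order: np.ndarray,
    common_cols: np.ndarray,
    rare_indicator: np.ndarray,
    chrom_groups: list[np.ndarray],
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_perm`` sign assignments and return permuted (C, R_t)."""
    F = score_matrix.D.shape[0]
    bits = rng.integers(0, 2, size=(n_perm, F, len(chrom_groups)), dtype=np.int8)
    signs = (bits.astype(np.float32) * 2.0) - 1.0
    return _batch_stats(score_matrix.D, signs, chrom_groups, common_cols, order, rare_indicator)


def standardize_and_maximize(
    observed_M_t: np.ndarray, perm_M_t: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    """Standardise each threshold's statistic by its permutation mean/SD
    and take the max.  Degenerate thresholds (permutation SD = 0) are set
    to 0 on both sides."""
    mean = perm_M_t.mean(axis=0)
    sd = perm_M_t.std(axis=0, ddof=1)
    ok = sd > 0
    z_obs = np.where(ok, (observed_M_t - mean) / np.where(ok, sd, 1.0), 0.0)
    z_perm = np.where(ok[None, :], (perm_M_t - mean) / np.where(ok, sd, 1.0), 0.0)
    M = float(z_obs.max())
    return z_obs, M, z_perm.max(axis=1)


def ovpdt_test(
    cohort,
    region_indices: np.ndarray | None = None,
    config: PermutationConfig | None = None,
    region: str = "region",
    lr: np.ndarray | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    common_cut: float = COMMON_CUT,
    score_matrix: FamilyScoreMatrix | None = None,
) -> OVPDTResult:
    """Run the full test for one region of a cohort.

    ``lr`` may be precomputed; otherwise it is estimated here (and, being a
    function of parental mating types only, is never recomputed inside the
    permutation loop).
    """
    config = config or PermutationConfig()
    if region_indices is None:
        region_indices = np.arange(cohort.n_variants)
    region_indices = np.asarray(region_indices, int)

    if score_matrix is None:
        score_matrix = family_score_matrix(cohort)
    D = score_matrix.D[:, region_indices]
    maf = cohort.maf[region_indices]
    pos = cohort.pos[region_indices]
    chroms = cohort.chrom[region_indices]
    sub = FamilyScoreMatrix(D, score_matrix.n_T[:, region_indices],
                            score_matrix.n_S[:, region_indices])

    common_cols, rare = classify_variants(maf, common_cut, thresholds)
    n_rare = {t: int(len(rare[t])) for t in thresholds}
    rare_indicator = np.zeros((len(region_indices), len(thresholds)))
    for k, t in enumerate(thresholds):
        rare_indicator[rare[t], k] = 1.0

    den = (D ** 2).sum(axis=0)
    if not (den > 0).any():
        return OVPDTResult(region, len(common_cols), n_rare, 0.0, 1.0, 0,
                           {t: 0.0 for t in thresholds}, {t: 0.0 for t in thresholds},
                           {t: 0.0 for t in thresholds}, None, 0.0, 0, 0, 1.0,
                           testable=False)

    # counter-based seeding: (user seed, crc32 of region name) so regions
    # are reproducible independently of execution order / parallelism
    import zlib

    seed = config.seed
    entropy = seed.entropy if isinstance(seed, np.random.SeedSequence) else int(seed)
    region_key = zlib.crc32(region.encode())
    if lr is None:
        lr = lr_scores(cohort, region_indices[common_cols], B=config.grr_bootstrap,
                       seed=entropy, salt=(region_key, 1))
    lr = np.asarray(lr, float)

    X_obs = np.where(den > 0, D.sum(axis=0) ** 2 / np.maximum(den, 1e-300), 0.0)
    osr = ordered_subset_statistic(X_obs[common_cols], lr, pos[common_cols])
    R_obs = X_obs @ rare_indicator
    M_t_obs = R_obs + osr.C

    uniq = sorted(set(chroms.tolist()))
    chrom_groups = [np.flatnonzero(chroms == c) for c in uniq]

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=entropy, spawn_key=(region_key, 2))
    )
    perm_C = np.empty(0)
    perm_R = np.empty((0, len(thresholds)))
    K = 0
    exceedances = 0
    z_obs = np.zeros(len(thresholds))
    M = 0.0
    while True:
        batch = min(config.batch_size if K else max(config.min_K, config.batch_size),
                    config.max_K - K)
        C_b, R_b = permutation_null(sub, osr.order, common_cols, rare_indicator,
                                    chrom_groups, batch, rng)
        perm_C = np.concatenate([perm_C, C_b])
        perm_R = np.concatenate([perm_R, R_b])
        K += batch
        perm_M_t = perm_R + perm_C[:, None]
        z_obs, M, perm_M = standardize_and_maximize(M_t_obs, perm_M_t)
        exceedances = int((perm_M > M).sum())
        if (exceedances >= config.target_exceedances and K >= config.min_K) or K >= config.max_K:
            break

    std = {t: float(z_obs[k]) for k, t in enumerate(thresholds)}
    chosen = max(std, key=std.get) if std else None
    return OVPDTResult(
        region=region,
        n_common=int(len(common_cols)),
        n_rare=n_rare,
        C=osr.C,
        min_p=osr.min_p,
        subset_size=int(np.argmin(osr.p_values) + 1) if osr.p_values.size else 0,
        R={t: float(R_obs[k]) for k, t in enumerate(thresholds)},
        M_t={t: float(M_t_obs[k]) for k, t in enumerate(thresholds)},
        standardized=std,
        chosen_t=chosen,
        M=M,
        K=K,
        exceedances=exceedances,
        p_value=permutation_pvalue(exceedances, K),
        lr=lr,
    )
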