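"""Genotypic relative risks from parental mating types.

Under HWE and ascertainment on an affected child, the probability of an
(unordered) parental mating type (i, j) is proportional to

    P(i, j | affected) ∝ w_ij(q) * A_ij(r1, r2),

where w_ij is the HWE mating frequency at minor-allele frequency q and
A_ij = E[risk of a random child of that mating] with genotype relative
risks r1 = f1/f0, r2 = f2/f0:

    A_00 = 1            A_01 = (1 + r1)/2        A_02 = r1
    A_11 = (1+2r1+r2)/4 A_12 = (r1 + r2)/2       A_22 = r2

Four ratios of these probabilities cancel the allele-frequency factors and
depend on the GRRs alone:

    rho1 = m11 / m02          = (1 + 2 r1 + r2) / (2 r1)
    rho2 = m01^2 / (m00 m11)  = 4 (1 + r1)^2 / (1 + 2 r1 + r2)
    rho3 = m12^2 / (m11 m22)  = 4 (r1 + r2)^2 / ((1 + 2 r1 + r2) r2)
    rho4 = m02^2 / (m00 m22)  = 4 r1^2 / r2

r1 is fitted by a log-scale grid search over (0.5, 20) under the additive
penetrance constraint r2 = 2 r1 - 1, minimising the summed distance between
theoretical and observed ratios over the estimable ratios.  The normalised
score lr = log(r1) / sqrt(var_boot(log r1)) ranks common variants; it uses
parental data only, so it is exactly invariant under transmission
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MatingTypeCounts",
    "GRREstimate",
    "count_mating_types",
    "theoretical_ratios",
    "observed_ratios",
    "fit_grr",
    "bootstrap_var_log_r1",
    "normalized_lr",
    "lr_scores",
    "MATING_CELLS",
    "R1_GRID",
]

#: unordered parental dosage pairs, fixed cell order
MATING_CELLS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))
_CELL_INDEX = {c: k for k, c in enumerate(MATING_CELLS)}

# r1 grid over (0.5, 20), multiplicative steps of exp(0.005)
_N_GRID = int(np.floor(np.log(20.0 / 0.5) / 0.005))  # 737
R1_GRID = 0.5 * np.exp(0.005 * np.arange(1, _N_GRID + 1))

#: additive penetrance constraint f1 = (f0 + f2)/2  =>  r2 = 2 r1 - 1
def additive_r2(r1):
    return 2.0 * np.asarray(r1) - 1.0


@dataclass
class MatingTypeCounts:
    """Counts over the six unordered parental genotype pairs, among
    families with >=1 affected child and both parents typed."""

    counts: np.ndarray  # (6,) int64, MATING_CELLS order

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class GRREstimate:
    r1_hat: float | None
    r2_hat: float | None
    var_log_r1: float | None
    lr: float
    n_estimable_ratios: int


def count_mating_types(cohort, variant_index: int) -> MatingTypeCounts:
    """Tabulate parental dosage pairs at one site (families with an
    affected child; missing parents excluded)."""
    f = cohort.fathers[:, variant_index].astype(int)
    m = cohort.mothers[:, variant_index].astype(int)
    has_aff = cohort.affected.any(axis=1)
    ok = has_aff & (f >= 0) & (m >= 0)
    return MatingTypeCounts(_tabulate(f[ok], m[ok]))


def _tabulate(f: np.ndarray, m: np.ndarray) -> np.ndarray:
    lo = np.minimum(f, m)
    hi = np.maximum(f, m)
    code = np.array([[0, 1, 2], [1, 3, 4], [2, 4, 5]])[lo, hi]
    return np.bincount(code, minlength=6).astype(np.int64)


def _child_risk_factors(r1, r2):
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    return np.stack(
        [
            np.ones_like(r1),        # (0,0)
            (1.0 + r1) / 2.0,        # (0,1)
            r1,                      # (0,2)
            (1.0 + 2.0 * r1 + r2) / 4.0,  # (1,1)
            (r1 + r2) / 2.0,         # (1,2)
            r2,                      # (2,2)
        ],
        axis=-1,
    )


def theoretical_ratios(r1, r2) -> np.ndarray:
    """The four allele-frequency-free mating-type ratios at (r1, r2).

    Broadcasts over array-valued r1/r2; last axis indexes the ratios.
    """
    A = _child_risk_factors(r1, r2)
    a00, a01, a02, a11, a12, a22 = (A[..., k] for k in range(6))
    # HWE mating weights w00=p^4, w01=4p^3q, w02=2p^2q^2, w11=4p^2q^2,
    # w12=4pq^3, w22=q^4 cancel in these combinations:
    rho1 = 2.0 * a11 / a02
    rho2 = 4.0 * a01 ** 2 / (a00 * a11)
    rho3 = 4.0 * a12 ** 2 / (a11 * a22)
    rho4 = 4.0 * a02 ** 2 / (a00 * a22)
    return np.stack([rho1, rho2, rho3, rho4], axis=-1)


# numerator/denominator cell indices for each ratio, with powers
_RATIO_NUM = ((3,), (1, 1), (4, 4), (2, 2))
_RATIO_DEN = ((2,), (0, 3), (3, 5), (0, 5))


def observed_ratios(counts: MatingTypeCounts | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ratio estimates and estimability flags.

    A ratio is estimable iff every cell in its numerator and denominator
    has a positive count.  Works on a single (6,) vector or a (B, 6) batch.
    """
    c = counts.counts if isinstance(counts, MatingTypeCounts) else np.asarray(counts)
    c = np.asarray(c, float)
    single = c.ndim == 1
    if single:
        c = c[None, :]
    total = c.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = c / np.maximum(total, 1)
    vals = np.empty((c.shape[0], 4))
    est = np.empty((c.shape[0], 4), bool)
    for k, (num, den) in enumerate(zip(_RATIO_NUM, _RATIO_DEN)):
        num_p = np.prod(p[:, num], axis=1)
        den_p = np.prod(p[:, den], axis=1)
        ok = (c[:, num] > 0).all(axis=1) & (c[:, den] > 0).all(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[:, k] = np.where(ok, num_p / np.maximum(den_p, 1e-300), np.nan)
        est[:, k] = ok
    if single:
        return vals[0], est[0]
    return vals, est


_THEO_GRID: np.ndarray | None = None


def _theo_grid() -> np.ndarray:
    global _THEO_GRID
    if _THEO_GRID is None:
        _THEO_GRID = np.ascontiguousarray(
            theoretical_ratios(R1_GRID, additive_r2(R1_GRID)).astype(np.float32)
        )  # (G, 4)
    return _THEO_GRID


def _fit_r1_batch(obs: np.ndarray, est: np.ndarray) -> np.ndarray:
    """Grid-minimising r1 per row; NaN where no ratio is estimable.
    Distance = sum over estimable ratios of |theoretical - observed|; ties
    resolve to the smallest r1 (first grid index)."""
    theo = _theo_grid()  # (G, 4) float32
    B = obs.shape[0]
    dist = np.zeros((B, theo.shape[0]), np.float32)
    obs32 = obs.astype(np.float32)
    for k in range(4):
        col = np.abs(obs32[:, k, None] - theo[None, :, k])
        dist += np.where(est[:, k, None], col, np.float32(0.0))
    idx = dist.argmin(axis=1)
    r1 = R1_GRID[idx]
    return np.where(est.any(axis=1), r1, np.nan)


def fit_grr(counts: MatingTypeCounts | np.ndarray) -> GRREstimate:
    """Point estimate (r1_hat, r2_hat) from mating-type counts; no
    variance/lr (see :func:`bootstrap_var_log_r1`)."""
    obs, est = observed_ratios(counts)
    n_est = int(est.sum())
    if n_est == 0:
        return GRREstimate(None, None, None, 0.0, 0)
    r1 = float(_fit_r1_batch(obs[None, :], est[None, :])[0])
    return GRREstimate(r1, float(additive_r2(r1)), None, 0.0, n_est)


def bootstrap_var_log_r1(
    counts: MatingTypeCounts | np.ndarray,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
    min_successes: int = 10,
) -> float | None:
    """Multinomial bootstrap over the six cells (family total fixed);
    returns the sample variance of log r1_hat across resamples with a
    successful fit, or None if fewer than ``min_successes`` succeed."""
    c = counts.counts if isinstance(counts, MatingTypeCounts) else np.asarray(counts)
    n = int(c.sum())
    if n == 0:
        return None
    rng = np.random.default_rng(rng)
    samples = rng.multinomial(n, c / n, size=B)
    obs, est = observed_ratios(samples)
    r1 = _fit_r1_batch(obs, est)
    ok = np.isfinite(r1)
    if ok.sum() < min_successes:
        return None
    return float(np.var(np.log(r1[ok]), ddof=1))


def normalized_lr(r1_hat: float | None, var_log_r1: float | None) -> float:
    """lr = log(r1_hat)/sqrt(var); 0 when the estimate or a positive
    variance is unavailable.  Risk alleles give lr > 0, protective < 0."""
    if r1_hat is None or var_log_r1 is None or not var_log_r1 > 0:
        return 0.0
    return float(np.log(r1_hat) / np.sqrt(var_log_r1))


def lr_scores(
    cohort,
    variant_indices: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    salt: tuple[int, ...] = (1,),
) -> np.ndarray:
    """Normalised lr per variant (0 where unestimable).

    The bootstrap RNG is seeded per variant from (seed, salt, position) so
    results do not depend on variant order within the region.
    """
    out = np.zeros(len(variant_indices))
    for k, j in enumerate(variant_indices):
        mt = count_mating_types(cohort, int(j))
        estimate = fit_grr(mt)
        if estimate.r1_hat is None:
            continue
        v = cohort.variants[int(j)]
        child = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(*salt, v.pos))
        )
        var = bootstrap_var_log_r1(mt, B=B, rng=child)
        out[k] = normalized_lr(estimate.r1_hat, var)
    return out
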