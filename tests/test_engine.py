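import numpy as np
import pytest
from scipy.stats import chi2

from ovpdt.engine import (
    PermutationConfig,
    combined_statistic,
    ordered_subset_statistic,
    ovpdt_test,
    permutation_pvalue,
    rare_statistic,
    standardize_and_maximize,
    subset_order,
)
from ovpdt.families import Cohort, NuclearFamily
from conftest import make_variants


# ---------------------------------------------------------------------------
# ordered subset
# ---------------------------------------------------------------------------

def brute_force_C(X, lr, pos, alpha=0.05):
    """Independent oracle: evaluate every prefix of the |lr|-descending
    order explicitly."""
    order = subset_order(lr, X, pos)
    best_p, best_S = 1.0, 0.0
    for i in range(1, len(X) + 1):
        S = X[order[:i]].sum()
        p = chi2.sf(S, i)
        if p < best_p:
            best_p, best_S = p, S
    return (best_S if best_p <= alpha else 0.0), best_p


def test_single_variant_at_critical_value():
    # just below / above the chi2(1) 5% critical value 3.8415
    res = ordered_subset_statistic(np.array([3.85]), np.array([1.0]))
    assert res.min_p == pytest.approx(chi2.sf(3.85, 1))
    assert res.min_p <= 0.05 and res.C == pytest.approx(3.85)
    res = ordered_subset_statistic(np.array([3.83]), np.array([1.0]))
    assert res.min_p > 0.05 and res.C == 0.0


def test_two_variant_example():
    # X = [5.0, 0.1] in lr order: p1 = 0.02535, p2 = P(chi2_2 >= 5.1) = 0.07808
    res = ordered_subset_statistic(np.array([5.0, 0.1]), np.array([2.0, 1.0]))
    assert res.p_values[0] == pytest.approx(0.02535, abs=1e-5)
    assert res.p_values[1] == pytest.approx(0.07808, abs=1e-5)
    assert res.min_p == pytest.approx(0.02535, abs=1e-5)
    assert res.C == pytest.approx(5.0)


def test_all_zero_statistics():
    res = ordered_subset_statistic(np.zeros(4), np.zeros(4))
    assert (res.p_values == 1.0).all() and res.C == 0.0 and res.min_p == 1.0


def test_no_common_variants():
    res = ordered_subset_statistic(np.array([]), np.array([]))
    assert res.C == 0.0 and res.min_p == 1.0


def test_ordered_subset_matches_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(40):
        n = rng.integers(1, 21)
        X = rng.chisquare(1, n)
        lr = rng.normal(0, 2, n) * rng.integers(0, 2, n)  # some exact zeros
        pos = np.arange(n) * 17
        res = ordered_subset_statistic(X, lr, pos)
        C_bf, p_bf = brute_force_C(X, lr, pos)
        assert res.C == pytest.approx(C_bf, abs=1e-12)
        assert res.min_p == pytest.approx(p_bf, abs=1e-12)


def test_subset_order_tie_breaks():
    lr = np.array([0.0, 2.0, -2.0, 0.0])
    X = np.array([9.0, 1.0, 5.0, 1.0])
    pos = np.array([10, 20, 30, 40])
    # |lr| desc; tie at |lr|=2 -> larger X first; lr=0 block last, by X desc
    assert subset_order(lr, X, pos).tolist() == [2, 1, 0, 3]


# ---------------------------------------------------------------------------
# rare / combined / standardization / p-value arithmetic
# ---------------------------------------------------------------------------

def test_rare_statistic_sum_and_nesting():
    assert rare_statistic(np.array([1.2, 0.3, 2.0])) == pytest.approx(3.5)
    assert rare_statistic(np.array([])) == 0.0
    X = np.random.default_rng(0).chisquare(1, 50)
    maf = np.random.default_rng(1).uniform(0, 0.06, 50)
    R = {t: rare_statistic(X[maf < t]) for t in (0.005, 0.01, 0.03, 0.05)}
    assert R[0.005] <= R[0.01] <= R[0.03] <= R[0.05]


def test_combined_statistic():
    assert combined_statistic(3.5, 5.0) == 8.5
    assert combined_statistic(3.5, 0.0) == 3.5
    assert combined_statistic(0.0, 5.0) == 5.0


def test_standardize_and_maximize():
    rng = np.random.default_rng(4)
    perm = rng.normal(3.0, 2.0, size=(500, 4))
    obs = np.array([9.0, 3.0, 3.0, 1.0])
    z, M, perm_max = standardize_and_maximize(obs, perm)
    assert M == pytest.approx(z.max())
    z_perm0 = (perm - perm.mean(0)) / perm.std(0, ddof=1)
    np.testing.assert_allclose(z_perm0.max(1), perm_max)
    assert abs(z_perm0.mean()) < 0.05

    # single informative threshold reduces to a z-score
    perm1 = perm[:, :1]
    z1, M1, _ = standardize_and_maximize(obs[:1], perm1)
    assert M1 == pytest.approx((9.0 - perm1.mean()) / perm1.std(ddof=1))

    # degenerate threshold (zero permutation SD) is neutralized
    perm_deg = np.concatenate([perm[:, :1], np.full((500, 1), 7.0)], axis=1)
    z2, M2, _ = standardize_and_maximize(np.array([9.0, 7.0]), perm_deg)
    assert z2[1] == 0.0


def test_permutation_pvalue_arithmetic():
    assert permutation_pvalue(36, 2000) == pytest.approx(37 / 2001)
    assert permutation_pvalue(0, 2000) == pytest.approx(1 / 2001)  # floor
    assert 0 < permutation_pvalue(0, 10) <= 1
    assert permutation_pvalue(10, 10) == 1.0


# ---------------------------------------------------------------------------
# full test on small cohorts
# ---------------------------------------------------------------------------

def _random_trio_cohort(rng, n=80, V=12, chrom="1"):
    maf = rng.uniform(0.002, 0.4, V)
    f = rng.binomial(2, maf, (n, V)).astype(np.int8)
    m = rng.binomial(2, maf, (n, V)).astype(np.int8)
    c = ((f + rng.integers(0, 2, (n, V)) >= 2).astype(np.int8)
         + (m + rng.integers(0, 2, (n, V)) >= 2).astype(np.int8))
    fams = [NuclearFamily(f"F{i}", f[i], m[i], [(c[i], True)]) for i in range(n)]
    variants = make_variants(V, chrom)
    cohort = Cohort.from_families(fams, variants)
    return cohort


def test_ovpdt_determinism_and_bounds():
    rng = np.random.default_rng(8)
    cohort = _random_trio_cohort(rng)
    cfg = PermutationConfig(min_K=500, max_K=500, seed=11, grr_bootstrap=100)
    r1 = ovpdt_test(cohort, config=cfg, region="gene1")
    r2 = ovpdt_test(cohort, config=cfg, region="gene1")
    assert r1.p_value == r2.p_value and r1.M == r2.M and r1.K == r2.K
    assert 0 < r1.p_value <= 1
    assert r1.p_value == permutation_pvalue(r1.exceedances, r1.K)


def test_ovpdt_invariant_to_variant_order():
    rng = np.random.default_rng(9)
    cohort = _random_trio_cohort(rng, n=60, V=10)
    perm = np.random.default_rng(1).permutation(10)
    shuffled = Cohort(
        cohort.family_ids,
        [cohort.variants[j] for j in perm],
        cohort.fathers[:, perm],
        cohort.mothers[:, perm],
        cohort.children[:, :, perm],
        cohort.child_present,
        cohort.affected,
    )
    cfg = PermutationConfig(min_K=400, max_K=400, seed=5, grr_bootstrap=100)
    a = ovpdt_test(cohort, config=cfg, region="g")
    b = ovpdt_test(shuffled, config=cfg, region="g")
    assert a.p_value == b.p_value
    assert a.M == pytest.approx(b.M)


def test_untestable_region():
    # all parents homozygous -> no informative family anywhere
    fams = [
        NuclearFamily(f"F{i}", np.zeros(3, np.int8), np.full(3, 2, np.int8),
                      [(np.ones(3, np.int8), True)])
        for i in range(10)
    ]
    cohort = Cohort.from_families(fams, make_variants(3, maf=[0.5, 0.5, 0.5]))
    res = ovpdt_test(cohort, config=PermutationConfig(seed=1), region="r")
    assert not res.testable and res.p_value == 1.0


def test_adaptive_stopping_contract():
    rng = np.random.default_rng(10)
    cohort = _random_trio_cohort(rng, n=100, V=8)
    cfg = PermutationConfig(min_K=2000, max_K=6000, seed=3, grr_bootstrap=50)
    res = ovpdt_test(cohort, config=cfg, region="r")
    # stopped either because exceedances target was met after min_K, or at max_K
    assert res.K >= cfg.min_K
    if res.K < cfg.max_K:
        assert res.exceedances >= cfg.target_exceedances
    assert res.K <= cfg.max_K


def test_sign_flip_null_mean_zero():
    """Permuted numerators have mean ~0 per variant by sign symmetry."""
    from ovpdt.pdt import family_score_matrix

    rng = np.random.default_rng(12)
    cohort = _random_trio_cohort(rng, n=50, V=5)
    mat = family_score_matrix(cohort)
    signs = np.where(np.random.default_rng(0).random((4000, 50)) < 0.5, -1.0, 1.0)
    nums = signs @ mat.D
    sd = np.sqrt((mat.D ** 2).sum(0))
    assert (np.abs(nums.mean(0)) < 4 * sd / np.sqrt(4000) + 1e-12).all()
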