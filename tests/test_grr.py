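import itertools

import numpy as np
import pytest

from ovpdt.families import Cohort, NuclearFamily
from ovpdt.grr import (
    MATING_CELLS,
    R1_GRID,
    MatingTypeCounts,
    additive_r2,
    bootstrap_var_log_r1,
    count_mating_types,
    fit_grr,
    lr_scores,
    normalized_lr,
    observed_ratios,
    theoretical_ratios,
)
from conftest import make_variants


# ---------------------------------------------------------------------------
# enumeration oracle: P(mating type | affected child) from first principles
# ---------------------------------------------------------------------------

def mating_probs_oracle(r1, r2, q, f0=0.01):
    """Enumerate parental genotypes under HWE and child genotypes by
    explicit allele transmission; condition on an affected child."""
    geno_p = {0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q ** 2}
    pen = {0: f0, 1: f0 * r1, 2: f0 * r2}

    def child_dist(g):
        # alleles carried, each transmitted w.p. 1/2
        alleles = {0: [0, 0], 1: [0, 1], 2: [1, 1]}[g]
        return [(alleles[0], 0.5), (alleles[1], 0.5)]

    joint = {}
    for gf, gm in itertools.product(range(3), repeat=2):
        p_parents = geno_p[gf] * geno_p[gm]
        p_aff = 0.0
        for af, pf in child_dist(gf):
            for am, pm in child_dist(gm):
                p_aff += pf * pm * pen[af + am]
        cell = (min(gf, gm), max(gf, gm))
        joint[cell] = joint.get(cell, 0.0) + p_parents * p_aff
    total = sum(joint.values())
    return np.array([joint[c] / total for c in MATING_CELLS])


def ratios_from_probs(m):
    return np.array([
        m[3] / m[2],
        m[1] ** 2 / (m[0] * m[3]),
        m[4] ** 2 / (m[3] * m[5]),
        m[2] ** 2 / (m[0] * m[5]),
    ])


@pytest.mark.parametrize("r1,r2", [(1.0, 1.0), (2.0, 3.0), (0.8, 0.6), (1.5, 2.0)])
@pytest.mark.parametrize("q", [0.1, 0.3, 0.45])
def test_theoretical_ratios_match_enumeration_oracle(r1, r2, q):
    oracle = ratios_from_probs(mating_probs_oracle(r1, r2, q))
    np.testing.assert_allclose(theoretical_ratios(r1, r2), oracle, atol=1e-10)


def test_ratios_are_allele_frequency_free():
    for r1, r2 in [(1.0, 1.0), (2.0, 3.0), (0.7, 0.5)]:
        a = ratios_from_probs(mating_probs_oracle(r1, r2, 0.1))
        b = ratios_from_probs(mating_probs_oracle(r1, r2, 0.4))
        np.testing.assert_allclose(a, b, atol=1e-10)
        # and independent of the baseline penetrance
        c = ratios_from_probs(mating_probs_oracle(r1, r2, 0.25, f0=0.2))
        np.testing.assert_allclose(a, c, atol=1e-10)


def test_null_ratios_equal_no_association_values():
    np.testing.assert_allclose(
        theoretical_ratios(1.0, 1.0),
        ratios_from_probs(mating_probs_oracle(1.0, 1.0, 0.2)),
        atol=1e-12,
    )


# ---------------------------------------------------------------------------
# counting and observed ratios
# ---------------------------------------------------------------------------

def _cohort_from_parent_pairs(pairs):
    fams = [
        NuclearFamily(
            f"F{i}",
            np.array([f], np.int8),
            np.array([m], np.int8),
            [(np.array([min(f + m, 2) // 1 and 1 or 0], np.int8), True)],
        )
        for i, (f, m) in enumerate(pairs)
    ]
    # child genotype irrelevant for mating counts but must be Mendelian-legal
    for fam in fams:
        f, m = int(fam.father_genotypes[0]), int(fam.mother_genotypes[0])
        legal = max((f == 2) + (m == 2), 0)
        fam.children[0] = (np.array([legal], np.int8), True)
    return Cohort.from_families(fams, make_variants(1))


def test_count_mating_types_tabulation():
    cohort = _cohort_from_parent_pairs([(1, 1), (0, 1), (1, 1)])
    counts = count_mating_types(cohort, 0)
    assert counts.counts[MATING_CELLS.index((1, 1))] == 2
    assert counts.counts[MATING_CELLS.index((0, 1))] == 1
    assert counts.total == 3


def test_count_mating_types_matches_hwe_proportions():
    rng = np.random.default_rng(11)
    q, n = 0.3, 4000
    pairs = list(zip(rng.binomial(2, q, n), rng.binomial(2, q, n)))
    counts = count_mating_types(_cohort_from_parent_pairs(pairs), 0).counts
    expected = mating_probs_oracle(1.0, 1.0, q)  # null: ascertainment-free
    for k in range(6):
        se = np.sqrt(expected[k] * (1 - expected[k]) / n)
        assert abs(counts[k] / n - expected[k]) < 4 * se


def test_observed_ratios_estimability():
    full = np.array([10, 20, 5, 15, 8, 3])
    vals, est = observed_ratios(full)
    assert est.all() and np.isfinite(vals).all()

    no_homminor = np.array([10, 20, 0, 15, 0, 0])  # expected for rare variants
    vals, est = observed_ratios(no_homminor)
    assert est.tolist() == [False, True, False, False]

    empty = np.array([50, 0, 0, 0, 0, 0])
    vals, est = observed_ratios(empty)
    assert not est.any()
    assert fit_grr(empty).r1_hat is None and fit_grr(empty).lr == 0.0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r1", [0.8, 1.0, 1.5, 2.0, 3.0])
@pytest.mark.parametrize("q", [0.1, 0.3])
def test_fit_grr_recovers_r1_from_exact_proportions(r1, q):
    r2 = float(additive_r2(r1))
    probs = mating_probs_oracle(r1, r2, q)
    # exact analytic proportions at n = 1e6 (unrounded: near r1 = 1 the
    # additive model's risk/protective twin minima are close enough that
    # integer rounding of tiny cells can flip between them)
    counts = probs * 1_000_000
    est = fit_grr(counts)
    # within one multiplicative grid step of exp(0.005)
    assert abs(np.log(est.r1_hat / r1)) <= 0.0051
    assert est.n_estimable_ratios == 4


def test_fit_grr_protective_below_one():
    probs = mating_probs_oracle(0.8, 0.6, 0.3)
    est = fit_grr(np.round(probs * 1_000_000).astype(int))
    assert est.r1_hat < 1.0


def test_bootstrap_determinism_and_scaling():
    probs = mating_probs_oracle(2.0, 3.0, 0.3)
    c500 = np.round(probs * 500).astype(int)
    c2000 = np.round(probs * 2000).astype(int)
    v_a = bootstrap_var_log_r1(c500, B=400, rng=123)
    v_b = bootstrap_var_log_r1(c500, B=400, rng=123)
    v_c = bootstrap_var_log_r1(c500, B=400, rng=456)
    assert v_a == v_b and v_a != v_c
    # quadrupling n: variance drops, roughly 1/n but the distribution of
    # refits is a risk/protective mixture, so only within a factor ~2 of
    # the ideal halving-per-doubling
    v_big = bootstrap_var_log_r1(c2000, B=400, rng=123)
    assert 1.0 < v_a / v_big < 16.0

    degenerate = np.array([200, 0, 0, 0, 0, 0])
    assert bootstrap_var_log_r1(degenerate, B=100, rng=0) is None


@pytest.mark.parametrize("r1,var,expect", [
    (1.0, 0.5, 0.0),
    (2.0, 0.04, np.log(2.0) / 0.2),
    (None, None, 0.0),
])
def test_normalized_lr(r1, var, expect):
    assert normalized_lr(r1, var) == pytest.approx(expect, abs=1e-9)
    if r1 == 2.0:
        assert normalized_lr(2.0, 0.04) == pytest.approx(3.4657, abs=1e-3)


def test_lr_invariant_under_transmission_permutation():
    """lr uses parental mating types only, so permuting transmissions
    (child' = f + m - c) must leave it bit-identical."""
    rng = np.random.default_rng(5)
    n = 300
    f = rng.binomial(2, 0.3, (n, 1)).astype(np.int8)
    m = rng.binomial(2, 0.3, (n, 1)).astype(np.int8)
    half = np.where(rng.random((n, 1)) < 0.5, 1, 0)
    c = np.minimum(f, 1) * half + (f == 2) + 0  # one paternal allele
    c = (c + np.minimum(m, 1) * rng.integers(0, 2, (n, 1)) + (m == 2)).astype(np.int8)

    def build(child):
        fams = [
            NuclearFamily(f"F{i}", f[i], m[i], [(child[i], True)]) for i in range(n)
        ]
        return Cohort.from_families(fams, make_variants(1))

    lr1 = lr_scores(build(c), np.array([0]), B=200, seed=9)
    lr2 = lr_scores(build((f + m - c).astype(np.int8)), np.array([0]), B=200, seed=9)
    assert lr1[0] == lr2[0] and lr1[0] != 0.0


def test_rare_variant_unestimable_fraction_is_high():
    """At MAF 0.01 with 1000 trios, most variants lack the mating-type
    cells the ratios need."""
    rng = np.random.default_rng(21)
    unest = 0
    trials = 60
    for _ in range(trials):
        fm = rng.binomial(2, 0.01, (1000, 2))
        counts = MatingTypeCounts(
            np.bincount(
                np.array([[0, 1, 2], [1, 3, 4], [2, 4, 5]])[
                    np.minimum(fm[:, 0], fm[:, 1]), np.maximum(fm[:, 0], fm[:, 1])
                ],
                minlength=6,
            ).astype(np.int64)
        )
        if fit_grr(counts).r1_hat is None:
            unest += 1
    assert unest / trials > 0.5
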