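"""Family-sequencing disease simulator.

Cohorts are generated in three steps: (1) a coalescent haplotype pool with
a sequencing-like site-frequency spectrum, (2) a logistic penetrance model
(prevalence 5%) with MAF-dependent rare-variant odds ratios and
Uniform(1.05, 1.3) common-variant odds ratios, (3) Mendelian transmission
and rejection sampling on the family's affection pattern.

The pool replaces cosi with msprime, using a joint Africa/Europe history
in the style of the published cosi best-fit model: ancestral N=12,500
splitting into an African branch (N=24,000) and a European branch with
two brief bottlenecks (~0.085 inbreeding each, at ~3,500 and ~2,000
generations) and exponential expansion from 7,700 to 100,000 over the
last 350 generations, with symmetric migration and short-tract gene
conversion alongside crossover.  The mutation rate was calibrated against
the target anchors -- a mean of ~198 polymorphic sites per 10 kb region
of which ~166 have MAF < 0.01 (and ~512 / ~429 per 25 kb) -- measured on
pools of 10,000 haplotypes.  The anchors are sample-size dependent, so
the pool size is part of the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .families import Cohort, VariantRecord

__all__ = [
    "HaplotypePool",
    "DiseaseModel",
    "Scenario",
    "SCENARIOS",
    "build_pool",
    "load_pool",
    "assign_effects",
    "calibrate_intercept",
    "simulate_cohort",
    "write_vcf",
    "write_fam",
    "write_pool",
    "rare_effect_beta",
    "EFFECT_COEF",
]

# --- frozen demographic calibration (see module docstring) ---------------
# Two-population history in the style of the published cosi best-fit
# model: ancestral N=12,500 splitting ~3,600 generations ago into an
# African branch (N=24,000) and a European branch with two brief
# bottlenecks (inbreeding coefficient ~0.085 each, at ~3,500 and ~2,000
# generations) and recent expansion from 7,700 to 100,000 starting 350
# generations ago; symmetric Africa<->Europe migration; crossover plus
# short-tract gene conversion.  Mutation rate calibrated to the
# variant-count anchors on pools of 10,000 haplotypes.
_MU = 2.05e-8
_RECOMB = 1e-8
_GC_RATE = 1.0e-8
_GC_TRACT = 500
_MIGRATION = 3e-5
_N_PRESENT = 100_000
_T_GROWTH = 350
_N_RECENT = 7_700
_T_BOTTLE2 = 2_000          # European-specific bottleneck
_N_BOTTLE2 = 800
_DUR_BOTTLE2 = 135
_T_BOTTLE1 = 3_500          # out-of-Africa bottleneck
_N_BOTTLE1 = 600
_DUR_BOTTLE1 = 100
_N_AFR = 24_000
_N_ANC = 12_500
#: default pool size (haplotypes per population); part of the calibration
POOL_HAPLOTYPES = 10_000

#: rare-variant effect: beta = EFFECT_COEF * |log10 MAF| (odds ratio 5 at
#: MAF 1e-4), the standard SKAT-family choice
EFFECT_COEF = float(np.log(5.0) / 4.0)

#: rare/common boundary used by the *simulation* effect model
SIM_RARE_CUT = 0.01

PREVALENCE = 0.05


def rare_effect_beta(maf: np.ndarray) -> np.ndarray:
    """MAF-dependent log odds ratio for rare risk variants."""
    return EFFECT_COEF * np.abs(np.log10(np.asarray(maf, float)))


@dataclass
class HaplotypePool:
    """Binary haplotype matrix (haplotype x site), sites folded so allele
    1 is the pool minor allele."""

    haplotypes: np.ndarray        # (H, V) int8 in {0, 1}
    positions: np.ndarray         # (V,) 1-based int
    chrom: str
    population: np.ndarray        # (H,) str labels

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class DiseaseModel:
    """Logistic penetrance P(affected | g) = expit(alpha + beta . g)."""

    alpha: float
    beta: np.ndarray
    prevalence: float = PREVALENCE


@dataclass(frozen=True)
class Scenario:
    """One simulation configuration (named presets mirror Scen1-Scen22)."""

    name: str
    region_kb: int                      # 10 or 25
    n_families: int
    structure: str = "A"                # A | AUU | AA
    populations: tuple[tuple[str, int], ...] = (("european", -1),)
    causal_rare_frac: float = 0.0
    causal_common_frac: float = 0.0
    protective_frac: float = 0.0

    def __post_init__(self):
        if self.structure not in ("A", "AUU", "AA"):
            raise ValueError(f"unknown family structure {self.structure!r}")
        if self.populations == (("european", -1),):
            object.__setattr__(self, "populations", (("european", self.n_families),))
        if sum(n for _, n in self.populations) != self.n_families:
            raise ValueError("population family counts must sum to n_families")


def _scen(name, kb, n, structure="A", pops=None, rare=0.0, common=0.0, prot=0.0):
    pops = pops or (("european", n),)
    return Scenario(name, kb, n, structure, tuple(pops), rare, common, prot)


SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        _scen("Scen1", 10, 500),
        _scen("Scen2", 10, 1000),
        _scen("Scen3", 10, 1000, "AUU"),
        _scen("Scen4", 10, 1000, "AA"),
        _scen("Scen5", 25, 500),
        _scen("Scen6", 25, 1000),
        _scen("Scen7", 25, 1000, "AUU"),
        _scen("Scen8", 25, 1000, "AA"),
        _scen("Scen9", 10, 1000, "A", (("european", 700), ("african", 300))),
        _scen("Scen10", 25, 1000, "A", (("european", 700), ("african", 300))),
        _scen("Scen11", 10, 1000, rare=0.3),
        _scen("Scen12", 10, 1000, rare=0.3, prot=0.3),
        _scen("Scen13", 10, 1000, common=0.3),
        _scen("Scen14", 10, 1000, rare=0.1, common=0.1),
        _scen("Scen15", 10, 1000, rare=0.3, common=0.3),
        _scen("Scen16", 10, 1000, rare=0.3, common=0.3, prot=0.3),
        _scen("Scen17", 25, 1000, rare=0.3),
        _scen("Scen18", 25, 1000, rare=0.3, prot=0.3),
        _scen("Scen19", 25, 1000, common=0.3),
        _scen("Scen20", 25, 1000, rare=0.1, common=0.1),
        _scen("Scen21", 25, 1000, rare=0.3, common=0.3),
        _scen("Scen22", 25, 1000, rare=0.3, common=0.3, prot=0.3),
    ]
}


# ---------------------------------------------------------------------------
# haplotype pools
# ---------------------------------------------------------------------------

def _demography():
    """Joint Africa/Europe model; 'european' pools sample the EUR branch
    of this same model (matching how a joint best-fit model is used)."""
    import msprime

    growth = np.log(_N_PRESENT / _N_RECENT) / _T_GROWTH
    dem = msprime.Demography()
    dem.add_population(name="EUR", initial_size=_N_PRESENT, growth_rate=growth)
    dem.add_population(name="AFR", initial_size=_N_AFR)
    dem.add_population(name="ANC", initial_size=_N_ANC)
    dem.add_population_parameters_change(
        time=_T_GROWTH, growth_rate=0, initial_size=_N_RECENT, population="EUR")
    dem.add_population_parameters_change(
        time=_T_BOTTLE2, initial_size=_N_BOTTLE2, population="EUR")
    dem.add_population_parameters_change(
        time=_T_BOTTLE2 + _DUR_BOTTLE2, initial_size=_N_RECENT, population="EUR")
    dem.add_population_parameters_change(
        time=_T_BOTTLE1, initial_size=_N_BOTTLE1, population="EUR")
    dem.set_symmetric_migration_rate(["EUR", "AFR"], _MIGRATION)
    dem.add_population_split(
        time=_T_BOTTLE1 + _DUR_BOTTLE1, derived=["EUR", "AFR"], ancestral="ANC")
    dem.sort_events()
    return dem


def build_pool(
    region_kb: int,
    population: str = "european",
    seed: int = 1,
    n_haplotypes: int = POOL_HAPLOTYPES,
) -> HaplotypePool:
    """Simulate one region's haplotype pool.

    ``population`` is 'european', 'african', or 'admixed' (a two-population
    pool sharing one site list, half EUR / half AFR haplotypes).
    """
    import msprime

    L = region_kb * 1000
    if population == "european":
        samples = {"EUR": n_haplotypes // 2}
    elif population == "african":
        samples = {"AFR": n_haplotypes // 2}
    elif population == "admixed":
        samples = {"EUR": n_haplotypes // 4, "AFR": n_haplotypes // 4}
    else:
        raise ValueError(f"unknown population {population!r}")
    seed = int(seed) % (2 ** 31 - 2) + 1
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=_demography(),
        sequence_length=L,
        recombination_rate=_RECOMB,
        gene_conversion_rate=_GC_RATE,
        gene_conversion_tract_length=_GC_TRACT,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts, rate=_MU, random_seed=seed + 1, model=msprime.BinaryMutationModel()
    )
    G = ts.genotype_matrix().T.astype(np.int8)  # haplotypes x sites
    pos = ts.tables.sites.position.astype(int) + 1
    sample_nodes = ts.samples()
    labels = np.full(len(sample_nodes), "EUR", dtype="<U3")
    if len(ts.tables.populations) > 1:
        node_pop = ts.tables.nodes.population[sample_nodes]
        for pop in ts.populations():
            name = (pop.metadata or {}).get("name", str(pop.id))
            labels[node_pop == pop.id] = name
    freq = G.mean(axis=0)
    flip = freq > 0.5
    G[:, flip] = 1 - G[:, flip]
    poly = G.mean(axis=0) > 0
    # de-duplicate positions (msprime can stack mutations at one site)
    keep = poly & np.concatenate([[True], np.diff(pos) > 0])
    return HaplotypePool(G[:, keep], pos[keep], "1", labels)


def write_pool(pool: HaplotypePool, path: str) -> None:
    """Plain-text pool: header line of positions, then one 0/1 haplotype
    string per line prefixed by its population label."""
    with open(path, "w") as fh:
        fh.write("#chrom=" + pool.chrom + "\n")
        fh.write("#pos=" + ",".join(map(str, pool.positions)) + "\n")
        for lab, row in zip(pool.population, pool.haplotypes):
            fh.write(lab + "\t" + "".join(map(str, row)) + "\n")


def load_pool(path: str) -> HaplotypePool:
    chrom = "1"
    positions = None
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#chrom="):
                chrom = line.strip().split("=", 1)[1]
            elif line.startswith("#pos="):
                positions = np.array(line.strip().split("=", 1)[1].split(","), int)
            elif line.strip():
                lab, hap = line.split()
                labels.append(lab)
                rows.append(np.frombuffer(hap.encode(), np.uint8) - ord("0"))
    H = np.array(rows, np.int8)
    if positions is None:
        positions = np.arange(1, H.shape[1] + 1)
    return HaplotypePool(H, positions, chrom, np.array(labels))


# ---------------------------------------------------------------------------
# disease model
# ---------------------------------------------------------------------------

def assign_effects(pool: HaplotypePool, scenario: Scenario, rng) -> np.ndarray:
    """Per-site log odds ratios under a scenario.

    Rare class = pool MAF < 0.01, common class = the rest.  Causal sites
    are a uniform draw within each class; rare risk betas follow the
    MAF-dependent function, common risk ORs are Uniform(1.05, 1.3); a
    ``protective_frac`` share of all causal sites has its OR inverted.
    """
    rng = np.random.default_rng(rng)
    maf = pool.maf
    beta = np.zeros(pool.n_sites)
    rare_idx = np.flatnonzero(maf < SIM_RARE_CUT)
    common_idx = np.flatnonzero(maf >= SIM_RARE_CUT)
    causal: list[int] = []
    if scenario.causal_rare_frac > 0:
        k = int(round(scenario.causal_rare_frac * rare_idx.size))
        if rare_idx.size == 0:
            raise ValueError("no rare sites in pool but causal_rare_frac > 0")
        chosen = rng.choice(rare_idx, size=k, replace=False)
        beta[chosen] = rare_effect_beta(maf[chosen])
        causal.extend(chosen.tolist())
    if scenario.causal_common_frac > 0:
        k = int(round(scenario.causal_common_frac * common_idx.size))
        if common_idx.size == 0:
            raise ValueError("no common sites in pool but causal_common_frac > 0")
        chosen = rng.choice(common_idx, size=k, replace=False)
        beta[chosen] = np.log(rng.uniform(1.05, 1.3, size=k))
        causal.extend(chosen.tolist())
    if scenario.protective_frac > 0 and causal:
        k = int(round(scenario.protective_frac * len(causal)))
        flip = rng.choice(np.array(causal), size=k, replace=False)
        beta[flip] *= -1.0
    return beta


def calibrate_intercept(
    pool: HaplotypePool,
    beta: np.ndarray,
    prevalence: float = PREVALENCE,
    rng=None,
    n_pairs: int = 100_000,
    tol: float = 1e-4,
) -> float:
    """Solve alpha so the population prevalence of expit(alpha + beta.g)
    is ``prevalence`` (individuals = random haplotype pairs from the pool)."""
    if not np.any(beta):
        return float(logit(prevalence))
    rng = np.random.default_rng(rng)
    s = pool.haplotypes @ beta  # per-haplotype score
    i = rng.integers(0, pool.n_haplotypes, size=n_pairs)
    j = rng.integers(0, pool.n_haplotypes, size=n_pairs)
    pair = s[i] + s[j]

    def f(alpha):
        return expit(alpha + pair).mean() - prevalence

    lo, hi = logit(prevalence) - pair.max() - 1, logit(prevalence) - pair.min() + 1
    return float(brentq(f, lo, hi, xtol=tol))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_N_KIDS = {"A": 1, "AUU": 3, "AA": 2}


def _accept(structure: str, aff: np.ndarray) -> np.ndarray:
    """Affection-pattern filter; ``aff`` is (B, n_kids) booleans."""
    if structure == "A":
        return aff[:, 0]
    if structure == "AA":
        return aff.all(axis=1)
    return aff.sum(axis=1) == 1  # AUU: exactly one affected of three


def simulate_cohort(
    scenario: Scenario,
    seed: int = 1,
    pool: HaplotypePool | None = None,
    model: DiseaseModel | None = None,
    max_tries_per_family: int = 100_000,
) -> Cohort:
    """Draw an ascertained cohort under a scenario.

    Parents are random pool haplotype pairs (within their population);
    each child inherits one whole haplotype per parent (no intra-region
    recombination over 10-25 kb).  Families are rejection-sampled until
    the structure's affection pattern holds.
    """
    ss = np.random.SeedSequence(int(seed))
    pool_rng, eff_rng, fam_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    multi_pop = len(scenario.populations) > 1
    if pool is None:
        pool = build_pool(
            scenario.region_kb,
            "admixed" if multi_pop else scenario.populations[0][0],
            seed=int(pool_rng.integers(1, 2 ** 31 - 2)),
        )
    if model is None:
        beta = assign_effects(pool, scenario, eff_rng)
        alpha = calibrate_intercept(pool, beta, rng=eff_rng)
        model = DiseaseModel(alpha, beta)

    H = pool.haplotypes
    s_hap = H @ model.beta
    n_kids = _N_KIDS[scenario.structure]
    pop_of = {"european": "EUR", "african": "AFR"}

    fam_count = 0
    fathers_l, mothers_l, kids_l = [], [], []
    attempts_total = 0
    for pop_name, n_fam in scenario.populations:
        idx_pool = (
            np.flatnonzero(pool.population == pop_of.get(pop_name, pop_name))
            if multi_pop
            else np.arange(pool.n_haplotypes)
        )
        if idx_pool.size == 0:
            raise ValueError(f"pool has no haplotypes for population {pop_name!r}")
        need = n_fam
        got_f, got_m, got_k = [], [], []
        attempts = 0
        while need > 0:
            guess = max(int(need / max(PREVALENCE ** aff_min(scenario), 1e-4)), 200)
            B = min(guess, 200_000)
            attempts += B
            if attempts > max_tries_per_family * n_fam:
                raise RuntimeError(
                    f"ascertainment rejection rate pathological for {scenario.name}"
                )
            par = fam_rng.choice(idx_pool, size=(B, 4))  # f1 f2 m1 m2
            which_f = fam_rng.integers(0, 2, size=(B, n_kids))
            which_m = fam_rng.integers(0, 2, size=(B, n_kids))
            rows = np.arange(B)[:, None]
            pat = par[rows, which_f]          # (B, n_kids) paternal hap index
            mat = par[rows, 2 + which_m]
            score = s_hap[pat] + s_hap[mat]
            aff = fam_rng.random((B, n_kids)) < expit(model.alpha + score)
            ok = np.flatnonzero(_accept(scenario.structure, aff))[:need]
            got_f.append(par[ok, :2])
            got_m.append(par[ok, 2:])
            got_k.append((pat[ok], mat[ok], aff[ok]))
            need -= ok.size
        attempts_total += attempts
        fpar = np.concatenate([g for g in got_f])
        mpar = np.concatenate([g for g in got_m])
        pat = np.concatenate([g[0] for g in got_k])
        mat = np.concatenate([g[1] for g in got_k])
        aff = np.concatenate([g[2] for g in got_k])
        fathers_l.append(H[fpar[:, 0]] + H[fpar[:, 1]])
        mothers_l.append(H[mpar[:, 0]] + H[mpar[:, 1]])
        kids_l.append((H[pat] + H[mat], aff))
        fam_count += n_fam

    fathers = np.concatenate(fathers_l).astype(np.int8)
    mothers = np.concatenate(mothers_l).astype(np.int8)
    children = np.concatenate([k for k, _ in kids_l]).astype(np.int8)  # (F, n_kids, V)
    affected = np.concatenate([a for _, a in kids_l])
    if children.ndim == 2:
        children = children[:, None, :]
        affected = affected[:, None] if affected.ndim == 1 else affected

    # analysis-side variant records: MAF from parental genotypes, recoded
    # to the parental minor allele
    par_freq = (fathers.sum(0) + mothers.sum(0)) / (4.0 * fam_count)
    flip = par_freq > 0.5
    fathers[:, flip] = 2 - fathers[:, flip]
    mothers[:, flip] = 2 - mothers[:, flip]
    children[:, :, flip] = 2 - children[:, :, flip]
    par_freq = np.where(flip, 1.0 - par_freq, par_freq)
    keep = np.flatnonzero(par_freq > 0)
    variants = [
        VariantRecord(
            f"{pool.chrom}:{pool.positions[j]}", pool.chrom, int(pool.positions[j]),
            "1" if not flip[j] else "0", "0" if not flip[j] else "1",
            float(par_freq[j]),
        )
        for j in keep
    ]
    F = fam_count
    present = np.ones((F, n_kids), bool)
    cohort = Cohort(
        [f"F{i+1}" for i in range(F)],
        variants,
        fathers[:, keep],
        mothers[:, keep],
        children[:, :, keep],
        present,
        affected,
    )
    cohort.ascertainment_rate = fam_count / max(attempts_total, 1)  # type: ignore[attr-defined]
    cohort.model = model  # type: ignore[attr-defined]
    cohort.pool_site_index = keep  # type: ignore[attr-defined]
    return cohort


def aff_min(scenario: Scenario) -> int:
    """Minimum number of affected children the pattern requires (used only
    to size rejection-sampling batches)."""
    return {"A": 1, "AUU": 1, "AA": 2}[scenario.structure]


# ---------------------------------------------------------------------------
# writers (round-trip with ovpdt.families readers)
# ---------------------------------------------------------------------------

def write_fam(cohort: Cohort, path: str) -> None:
    with open(path, "w") as fh:
        for i, fid in enumerate(cohort.family_ids):
            fh.write(f"{fid}\t{fid}_fa\t0\t0\t1\t1\n")
            fh.write(f"{fid}\t{fid}_mo\t0\t0\t2\t1\n")
            for k in range(cohort.children.shape[1]):
                if not cohort.child_present[i, k]:
                    continue
                status = 2 if cohort.affected[i, k] else 1
                fh.write(f"{fid}\t{fid}_c{k+1}\t{fid}_fa\t{fid}_mo\t0\t{status}\n")


def write_vcf(cohort: Cohort, path: str) -> None:
    """Minimal VCF 4.2 with GT fields; REF = major allele label 'A',
    ALT = minor allele label 'T' (dosage counts ALT = minor)."""
    sample_names: list[str] = []
    cols: list[np.ndarray] = []
    for i, fid in enumerate(cohort.family_ids):
        sample_names += [f"{fid}_fa", f"{fid}_mo"]
        cols += [cohort.fathers[i], cohort.mothers[i]]
        for k in range(cohort.children.shape[1]):
            if cohort.child_present[i, k]:
                sample_names.append(f"{fid}_c{k+1}")
                cols.append(cohort.children[i, k])
    G = np.stack(cols)  # samples x variants
    gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in cohort.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for j, v in enumerate(cohort.variants):
            row = "\t".join(gt[int(g)] for g in G[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\tA\tT\t.\tPASS\t.\tGT\t{row}\n")
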