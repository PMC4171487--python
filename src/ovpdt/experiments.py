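"""Type I error and power experiments over simulated replicate cohorts.

Each replicate draws a fresh haplotype pool, a fresh effect assignment and
a fresh ascertained cohort, then runs the full OVPDT test on the whole
region.  Replicate seeds are counter-based (derived from the experiment
seed and the replicate index), so reports are bit-reproducible and
independent of any parallel execution order.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from .engine import PermutationConfig, ovpdt_test
from .simulate import SCENARIOS, Scenario, simulate_cohort

__all__ = ["ExperimentReport", "run_type1", "run_power", "run_experiment", "binom_ci"]


def binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    a = (1 - level) / 2
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - a, k + 1, n - k))
    return lo, hi


@dataclass
class ExperimentReport:
    scenario: str
    kind: str                      # "type1" | "power"
    n_replicates: int
    alphas: tuple[float, ...]
    rejections: dict[float, int]
    rejection_rate: dict[float, float]
    ci95: dict[float, tuple[float, float]]
    seed: int
    p_values: list[float] = field(repr=False, default_factory=list)
    mean_K: float = 0.0
    runtime_s: float = 0.0

    def to_json(self, path: str | None = None) -> str:
        d = asdict(self)
        d["alphas"] = list(self.alphas)
        d["rejections"] = {str(k): v for k, v in self.rejections.items()}
        d["rejection_rate"] = {str(k): v for k, v in self.rejection_rate.items()}
        d["ci95"] = {str(k): list(v) for k, v in self.ci95.items()}
        s = json.dumps(d, indent=1)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def run_experiment(
    scenario: Scenario | str,
    n_replicates: int,
    alphas: tuple[float, ...],
    seed: int,
    kind: str,
    null_override: bool = False,
    max_K: int = 20_000,
    grr_bootstrap: int = 200,
) -> ExperimentReport:
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if null_override:
        scenario = Scenario(
            scenario.name, scenario.region_kb, scenario.n_families,
            scenario.structure, scenario.populations, 0.0, 0.0, 0.0,
        )
    t0 = time.time()
    pvals = np.empty(n_replicates)
    Ks = np.empty(n_replicates)
    for rep in range(n_replicates):
        rep_seed = int(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(rep,)).generate_state(1)[0]
            % (2 ** 31 - 1)
        )
        cohort = simulate_cohort(scenario, seed=rep_seed)
        cfg = PermutationConfig(seed=rep_seed, max_K=max_K, grr_bootstrap=grr_bootstrap)
        res = ovpdt_test(cohort, config=cfg, region=scenario.name)
        pvals[rep] = res.p_value
        Ks[rep] = res.K
    rej = {a: int((pvals <= a).sum()) for a in alphas}
    return ExperimentReport(
        scenario=scenario.name,
        kind=kind,
        n_replicates=n_replicates,
        alphas=tuple(alphas),
        rejections=rej,
        rejection_rate={a: rej[a] / n_replicates for a in alphas},
        ci95={a: binom_ci(rej[a], n_replicates) for a in alphas},
        seed=int(seed),
        p_values=[float(p) for p in pvals],
        mean_K=float(Ks.mean()),
        runtime_s=time.time() - t0,
    )


def run_type1(
    scenario: Scenario | str,
    n_replicates: int = 2000,
    alphas: tuple[float, ...] = (0.05, 0.01),
    seed: int = 1,
    **kw,
) -> ExperimentReport:
    """Null rejection rates.  Effect fractions are forced to zero so any
    preset (including power presets) can be run as a null configuration."""
    return run_experiment(scenario, n_replicates, alphas, seed, "type1",
                          null_override=True, **kw)


def run_power(
    scenario: Scenario | str,
    n_replicates: int = 250,
    alpha: float = 0.05,
    seed: int = 1,
    **kw,
) -> ExperimentReport:
    kw.setdefault("max_K", 4000)
    return run_experiment(scenario, n_replicates, (alpha,), seed, "power", **kw)
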