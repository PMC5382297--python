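"""Synthetic genotype/phenotype generation and operating-characteristic runs.

Binary phenotypes follow a logistic model

    logit P(Y_i = 1) = log(0.01/0.99) + 0.64 E_i
                       + sum_j a_j G_ij + sum_j b_j E_i G_ij ,

with exposure ``E_i ~ N(0, 1)`` and eight SNPs drawn under Hardy-Weinberg
equilibrium with minor-allele frequencies redrawn per replicate from
U(0, 0.5).  Subjects are accrued one at a time until case and control
quotas are both met.  Continuous phenotypes drop the prevalence intercept
and add Gaussian noise:

    Y_i = 0.64 E_i + sum_j a_j G_ij + sum_j b_j E_i G_ij + eps,
    eps ~ N(0, sigma^2).

The null (type-I error) configuration fixes ``a = [1,1,-1,-1,0,0,0,0]`` and
``b = 0``; power scenarios redraw ``a_j ~ Bern(0.5) (1 - 2 Bern(0.5))``
each replicate and set ``b`` to a scenario template scaled by ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .model_core import ConvergenceError, DesignBundle, LOGIT, IDENTITY, LinkSpec
from .score_tests import MixGEResult, mixge_test

__all__ = [
    "SimulationScenario",
    "SimulationResult",
    "SimulationError",
    "gen_genotypes_hwe",
    "simulate_binary",
    "simulate_continuous",
    "simulate_bundle",
    "run_rejection_rate",
    "collect_null_pvalues",
    "scenario_presets",
    "NULL_A_VECTOR",
    "B_TEMPLATES",
    "C_GRIDS",
    "SIGMA2_GRIDS",
]

INTERCEPT_BINARY = float(np.log(0.01 / 0.99))
ENV_COEFF = 0.64
N_SNPS_DEFAULT = 8
MAF_FLOOR = 0.005          # avoids empty-variant degeneracy at MAF ~ 0
ACCRUAL_CAP = 10 ** 7      # max subjects drawn per replicate

NULL_A_VECTOR = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0, 0.0, 0.0])

B_TEMPLATES = {
    "burden": np.ones(8),
    "variance": np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0, 0.0, 0.0]),
    "mixed": np.array([1.0, 1.0, 0.0, 0.0, 0.5, 0.5, 0.5, 0.5]),
}

# effect-scale grids for the binary power scenarios, small/large samples
C_GRIDS = {
    ("burden", "small"): (0.4, 0.8, 1.2, 1.6, 2.0),
    ("burden", "large"): (0.05, 0.1, 0.15, 0.2, 0.25),
    ("variance", "small"): (0.4, 0.8, 1.2, 1.6, 2.0),
    ("variance", "large"): (0.1, 0.2, 0.3, 0.4, 0.5),
    ("mixed", "small"): (0.8, 1.6, 2.4, 3.2, 4.0),
    ("mixed", "large"): (0.1, 0.2, 0.3, 0.4, 0.5),
}

# noise-variance grids for the continuous power scenarios (C fixed at 1)
SIGMA2_GRIDS = {
    "small": (2.0, 4.0, 6.0, 8.0, 10.0),
    "large": (8.0, 16.0, 24.0, 32.0, 40.0),
}


class SimulationError(RuntimeError):
    """Subject accrual or phenotype generation failed."""


@dataclass
class SimulationScenario:
    """Generative configuration for one simulation condition."""

    phenotype_kind: str = "binary"          # "binary" | "continuous"
    n_cases: int = 100
    n_controls: int = 100
    n_subjects: int = 200                   # continuous only
    p_snps: int = N_SNPS_DEFAULT
    maf_low: float = 0.0
    maf_high: float = 0.5
    a_vector: np.ndarray | None = field(default_factory=lambda: NULL_A_VECTOR.copy())
    random_a: bool = False                  # redraw a_j each replicate (power runs)
    b_vector: np.ndarray | None = None      # None -> zero interaction (null)
    C: float = 0.0
    noise_variance: float = 1.0             # sigma^2, continuous only
    intercept: float = INTERCEPT_BINARY
    env_coeff: float = ENV_COEFF
    reps: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    c_grid: tuple[float, ...] | None = None
    sigma2_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.phenotype_kind not in ("binary", "continuous"):
            raise ValueError(f"unknown phenotype_kind {self.phenotype_kind!r}")
        if min(self.n_cases, self.n_controls, self.n_subjects, self.p_snps) <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.maf_low < self.maf_high <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 <= low < high <= 0.5")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def link(self) -> LinkSpec:
        return LOGIT if self.phenotype_kind == "binary" else IDENTITY

    def effective_b(self, rng: np.random.Generator | None = None) -> np.ndarray:
        if self.b_vector is None:
            return np.zeros(self.p_snps)
        return np.asarray(self.b_vector, dtype=float)

    def effective_a(self, rng: np.random.Generator) -> np.ndarray:
        if self.random_a:
            # a_j ~ Bernoulli(0.5) * (1 - 2 Bernoulli(0.5)): 0 w.p. 1/2, +-1 w.p. 1/4
            on = rng.random(self.p_snps) < 0.5
            sign = 1.0 - 2.0 * (rng.random(self.p_snps) < 0.5)
            return on * sign
        if self.a_vector is None:
            return np.zeros(self.p_snps)
        return np.asarray(self.a_vector, dtype=float)


@dataclass
class SimulationResult:
    """Empirical rejection rate with its Monte-Carlo standard error."""

    rejection_rate: float
    reps: int
    alpha: float
    per_method: dict[str, float] = field(default_factory=dict)

    @property
    def monte_carlo_se(self) -> float:
        r = self.rejection_rate
        return float(np.sqrt(r * (1.0 - r) / self.reps))


def gen_genotypes_hwe(n: int, p: int, maf_values: Sequence[float],
                      seed: int | np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg genotype matrix: per SNP j, P(2)=f^2, P(1)=2f(1-f), P(0)=(1-f)^2."""
    maf = np.asarray(maf_values, dtype=float)
    if maf.shape[0] != p or (maf < 0).any() or (maf > 0.5).any():
        raise ValueError("maf_values must be length p within [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random((n, p))
    # genotype = #{minor alleles}: two implicit Bernoulli(f) draws folded into one uniform
    p0 = (1.0 - maf) ** 2
    p01 = p0 + 2.0 * maf * (1.0 - maf)
    return ((u >= p0).astype(np.int8) + (u >= p01).astype(np.int8)).astype(float)


def _draw_maf(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    maf = rng.uniform(scenario.maf_low, scenario.maf_high, scenario.p_snps)
    return np.maximum(maf, MAF_FLOOR)


def simulate_binary(scenario: SimulationScenario,
                    rng: np.random.Generator | None = None) -> DesignBundle:
    """One binary-phenotype replicate with case/control quota accrual.

    Subjects are generated sequentially (vectorised in batches, selected in
    draw order) and assigned case/control by a Bernoulli trial on the
    inverse-logit of the linear predictor, until both quotas are met;
    overflow subjects are discarded.  The returned bundle has an
    intercept-only covariate matrix.
    """
    if scenario.phenotype_kind != "binary":
        raise ValueError("scenario is not binary")
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    maf = _draw_maf(scenario, rng)
    a = scenario.effective_a(rng)
    b = scenario.effective_b(rng)
    n_cases, n_controls = scenario.n_cases, scenario.n_controls
    need = n_cases + n_controls

    rows_y: list[np.ndarray] = []
    rows_e: list[np.ndarray] = []
    rows_g: list[np.ndarray] = []
    got_cases = got_controls = 0
    drawn = 0
    batch = 4 * need
    while got_cases < n_cases or got_controls < n_controls:
        if drawn >= ACCRUAL_CAP:
            raise SimulationError(
                f"case/control quota unreachable within {ACCRUAL_CAP} draws "
                f"(have {got_cases} cases, {got_controls} controls)"
            )
        batch = min(batch, ACCRUAL_CAP - drawn)
        e = rng.standard_normal(batch)
        g = gen_genotypes_hwe(batch, scenario.p_snps, maf, rng)
        eta = scenario.intercept + scenario.env_coeff * e + g @ a + e * (g @ b)
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.random(batch) < prob).astype(float)
        drawn += batch
        # retain only what is still needed, preserving draw order
        is_case = y == 1.0
        keep = np.zeros(batch, dtype=bool)
        ci = np.flatnonzero(is_case)[: n_cases - got_cases]
        ki = np.flatnonzero(~is_case)[: n_controls - got_controls]
        keep[ci] = True
        keep[ki] = True
        got_cases += ci.size
        got_controls += ki.size
        rows_y.append(y[keep])
        rows_e.append(e[keep])
        rows_g.append(g[keep])
        # size the next batch from the rarer outcome's observed rate
        if got_cases < n_cases or got_controls < n_controls:
            rate = max(min(is_case.mean(), 1 - is_case.mean()), 1.0 / batch)
            still = (n_cases - got_cases) + (n_controls - got_controls)
            batch = int(min(max(2 * still / rate, need), 5 * 10 ** 5))

    Y = np.concatenate(rows_y)[:need]
    E = np.concatenate(rows_e)[:need]
    G = np.vstack(rows_g)[:need]
    X = np.ones((need, 1))
    return DesignBundle(Y=Y, X=X, E=E, G=G)


def simulate_continuous(scenario: SimulationScenario,
                        rng: np.random.Generator | None = None) -> DesignBundle:
    """One continuous-phenotype replicate (no quota; Gaussian noise)."""
    if scenario.phenotype_kind != "continuous":
        raise ValueError("scenario is not continuous")
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    n = scenario.n_subjects
    maf = _draw_maf(scenario, rng)
    a = scenario.effective_a(rng)
    b = scenario.effective_b(rng)
    e = rng.standard_normal(n)
    g = gen_genotypes_hwe(n, scenario.p_snps, maf, rng)
    mean = scenario.env_coeff * e + g @ a + e * (g @ b)
    y = mean + rng.standard_normal(n) * np.sqrt(scenario.noise_variance)
    return DesignBundle(Y=y, X=np.ones((n, 1)), E=e, G=g)


def simulate_bundle(scenario: SimulationScenario,
                    rng: np.random.Generator | None = None) -> DesignBundle:
    if scenario.phenotype_kind == "binary":
        return simulate_binary(scenario, rng)
    return simulate_continuous(scenario, rng)


def _default_test(bundle: DesignBundle, link: LinkSpec) -> MixGEResult:
    return mixge_test(bundle, link, compute_random=False)


def collect_null_pvalues(scenario: SimulationScenario, reps: int | None = None,
                         test: Callable[[DesignBundle, LinkSpec], MixGEResult] | None = None,
                         ) -> dict[str, np.ndarray]:
    """Run ``reps`` replicates and collect all four p-values per replicate.

    Genotypes, MAFs and exposures are regenerated every replicate; each
    replicate consumes an independent child stream of the scenario seed, so
    results are reproducible and order-independent.
    """
    reps = reps if reps is not None else scenario.reps
    test = test or _default_test
    link = scenario.link
    streams = np.random.SeedSequence(scenario.seed).spawn(reps)
    out = {k: np.empty(reps) for k in ("p_pi", "p_tau", "p_fisher", "p_tippett")}
    for i, ss in enumerate(streams):
        # a replicate that separates the logistic fit (a rare variant
        # private to one outcome class) is redrawn from a child stream;
        # this happens on the order of 1 in 10^3-10^4 replicates and keeps
        # long null runs deterministic
        res = None
        for _attempt in range(20):
            rng = np.random.default_rng(ss)
            try:
                bundle = simulate_bundle(scenario, rng)
                res = test(bundle, link)
                break
            except ConvergenceError:
                ss = ss.spawn(1)[0]
            except Exception as exc:  # noqa: BLE001 - annotate replicate index
                raise SimulationError(f"replicate {i} failed: {exc}") from exc
        if res is None:
            raise SimulationError(f"replicate {i}: 20 consecutive separated fits")
        out["p_pi"][i] = res.p_pi
        out["p_tau"][i] = res.p_tau
        out["p_fisher"][i] = res.p_fisher
        out["p_tippett"][i] = res.p_tippett
    return out


def run_rejection_rate(scenario: SimulationScenario,
                       test: Callable[[DesignBundle, LinkSpec], MixGEResult] | None = None,
                       reps: int | None = None,
                       alpha: float | None = None) -> SimulationResult:
    """Empirical rejection proportion of the (pluggable) test at level alpha.

    The default test is the Fisher-combined MixGE; per-method rates for the
    component and Tippett-combined p-values are reported alongside.
    """
    reps = reps if reps is not None else scenario.reps
    alpha = alpha if alpha is not None else scenario.alpha
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pvals = collect_null_pvalues(scenario, reps=reps, test=test)
    rate = float((pvals["p_fisher"] < alpha).mean())
    per_method = {k: float((v < alpha).mean()) for k, v in pvals.items()}
    return SimulationResult(rate, reps, alpha, per_method)


def scenario_presets(name: str, phenotype_kind: str = "binary",
                     sample_size: str = "small",
                     C: float | None = None,
                     sigma2: float | None = None,
                     reps: int = 10_000, seed: int = 0) -> SimulationScenario:
    """Named power/null scenarios with their published effect grids.

    ``name`` is one of ``burden``, ``variance``, ``mixed`` (interaction
    templates scaled by C) or ``type1`` (a fixed, b = 0).  Power presets
    redraw the main effects ``a_j`` each replicate; continuous presets fix
    C = 1 and vary the noise variance instead.
    """
    if name not in ("type1", "burden", "variance", "mixed"):
        raise ValueError(f"unknown preset {name!r}")
    if sample_size not in ("small", "large"):
        raise ValueError("sample_size must be 'small' or 'large'")
    n_cc = 100 if sample_size == "small" else 1000
    n_sub = 200 if sample_size == "small" else 2000
    base = SimulationScenario(
        phenotype_kind=phenotype_kind, n_cases=n_cc, n_controls=n_cc,
        n_subjects=n_sub, reps=reps, seed=seed,
    )
    if name == "type1":
        return base
    template = B_TEMPLATES[name]
    if phenotype_kind == "binary":
        grid = C_GRIDS[(name, sample_size)]
        c = C if C is not None else grid[0]
        return replace(base, random_a=True, C=c, b_vector=c * template,
                       c_grid=grid)
    grid = SIGMA2_GRIDS[sample_size]
    s2 = sigma2 if sigma2 is not None else grid[0]
    return replace(base, random_a=True, C=1.0, b_vector=1.0 * template,
                   noise_variance=s2, sigma2_grid=grid)
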