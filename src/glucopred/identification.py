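"""Personalized parameter identification against a patient's CGMS record.

The fitness of a candidate parameter vector is the RMSE (mmol/l) between
the CGMS readings of a log window and a full continuous simulation of that
window, with model restarts at every fingerstick measurement.  Candidates
are expressed as dimensionless multipliers of the population-level
reference values, constrained to a clinically plausible band.

Four search strategies are provided, mirroring the practical pipeline
coarse-to-fine:

- one-factor-at-a-time (OFAT) sensitivity screening,
- exhaustive brute-force grid search (7 steps of 20% per parameter by
  default, i.e. multipliers 0.4 ... 1.6),
- a real-coded genetic algorithm with "fast" (pop 10 x gen 10, 1%
  mutation) and "slow" (pop 50 x gen 50, 20% mutation) presets, and
- Nelder-Mead downhill simplex refinement of a previous result.

All stochastic steps are driven by an explicit seed; candidate evaluation
is batched through the shared simulation engine, so the cost of a
population is one vectorized run per generation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import engine
from .absorption import AbsorptionParams
from .glycemia import PARAM_NAMES, GlycemiaParams, steady_state
from .lifestyle_log import PatientLog

__all__ = [
    "PRESET_PARAMS",
    "ParameterSpace",
    "TrainingConfig",
    "FitResult",
    "FitnessEvaluator",
    "fitness",
    "ofat_sensitivity",
    "brute_force",
    "ga_optimize",
    "nelder_mead_refine",
    "train",
]

#: Trainable parameter subsets by increasing size: the three most
#: influential parameters, the six with a sizable effect, and all nine.
PRESET_PARAMS: dict[int, tuple[str, ...]] = {
    3: ("K_xgi", "K_xi", "V_I"),
    6: ("K_xgi", "K_xi", "V_I", "T_GH", "V_G", "T_iGmax"),
    9: ("K_xgi", "K_xi", "V_I", "T_GH", "V_G", "T_iGmax", "tau_G", "G_star", "gamma"),
}


@dataclass(frozen=True)
class ParameterSpace:
    """An ordered subset of trainable parameters with multiplier bounds."""

    names: tuple[str, ...]
    reference: GlycemiaParams = field(default_factory=GlycemiaParams)
    lower: float = 0.2
    upper: float = 5.0

    def __post_init__(self) -> None:
        unknown = set(self.names) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        if not self.lower < 1.0 < self.upper:
            raise ValueError("multiplier bounds must contain 1.0")

    @classmethod
    def preset(
        cls, size: int, reference: GlycemiaParams | None = None, **kwargs
    ) -> "ParameterSpace":
        if size not in PRESET_PARAMS:
            raise ValueError(f"preset size must be one of {sorted(PRESET_PARAMS)}")
        if reference is None:
            reference = GlycemiaParams()
        return cls(PRESET_PARAMS[size], reference, **kwargs)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def clip(self, multipliers: np.ndarray) -> np.ndarray:
        return np.clip(multipliers, self.lower, self.upper)

    def apply(self, multipliers: np.ndarray | dict[str, float]) -> GlycemiaParams:
        """Reference parameters scaled by a multiplier vector."""
        if isinstance(multipliers, dict):
            return self.reference.with_multipliers(multipliers)
        return self.reference.with_multipliers(
            dict(zip(self.names, np.asarray(multipliers, dtype=float)))
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Search-method settings; the GA presets match the two pipeline modes."""

    method: str = "ga_slow"  # brute_force | ga_fast | ga_slow | nelder_mead_refine
    # brute force
    bf_steps: int = 7
    bf_step_size: float = 0.20
    bf_grid: str = "additive"  # additive | geometric
    # genetic algorithm
    population: int = 50
    generations: int = 50
    cx_prob: float = 0.90
    mut_prob: float = 0.20
    tournament_size: int = 3
    blend_alpha: float = 0.5
    mut_sigma: float = 0.1
    include_reference: bool = True
    # Nelder-Mead refinement
    nm_max_iter: int = 100
    seed: int = 0

    @classmethod
    def ga_fast(cls, seed: int = 0, **kwargs) -> "TrainingConfig":
        return cls(
            method="ga_fast", population=10, generations=10,
            cx_prob=0.90, mut_prob=0.01, seed=seed, **kwargs,
        )

    @classmethod
    def ga_slow(cls, seed: int = 0, **kwargs) -> "TrainingConfig":
        return cls(
            method="ga_slow", population=50, generations=50,
            cx_prob=0.90, mut_prob=0.20, seed=seed, **kwargs,
        )


@dataclass
class FitResult:
    """Outcome of one identification run."""

    multipliers: dict[str, float]
    params: GlycemiaParams
    fitness: float
    n_evaluations: int
    method: str
    trace: list[dict] = field(default_factory=list)

    def vector(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.multipliers[n] for n in names])


class FitnessEvaluator:
    """Batched RMSE fitness against one log window.

    The digestion/depot pass over the window is prepared once; each call
    simulates a (P, k) matrix of multiplier vectors in one vectorized run.
    An optional boolean ``sample_mask`` restricts the scored CGMS samples
    (used for per-period diurnal training); the simulation always covers
    the whole window.  Candidates whose trajectory loses finiteness get a
    +inf fitness instead of raising.
    """

    def __init__(
        self,
        log: PatientLog,
        space: ParameterSpace,
        absorption_params: AbsorptionParams | None = None,
        *,
        step: float = 1.0,
        profile=None,
        sample_mask: np.ndarray | None = None,
    ):
        cgms_times = log.cgms_times()
        if cgms_times.size == 0:
            raise ValueError("fitness requires CGMS measurements in the window")
        self.space = space
        self.profile = profile
        self.reference_values = log.cgms_values()
        self.sample_mask = (
            np.ones(cgms_times.size, dtype=bool) if sample_mask is None else sample_mask
        )
        self.prep = engine.prepare_window(
            log, absorption_params, step=step, restart=True, record_times=cgms_times
        )
        if self.prep.G0 is None:
            self.prep.G0 = steady_state(space.reference)[0]
        self.n_evaluations = 0

    def __call__(self, multipliers: np.ndarray) -> np.ndarray:
        multipliers = np.atleast_2d(np.asarray(multipliers, dtype=float))
        batch = engine.params_to_batch(self.space.reference, self.space.names, multipliers)
        out = engine.run_batch(self.prep, batch, profile=self.profile)
        with np.errstate(all="ignore"):
            err = out["G"][:, self.sample_mask] - self.reference_values[self.sample_mask]
            rmse = np.sqrt(np.mean(err * err, axis=1))
        rmse = np.where(out["ok"] & np.isfinite(rmse), rmse, np.inf)
        self.n_evaluations += multipliers.shape[0]
        return rmse

    def scalar(self, multipliers: np.ndarray) -> float:
        return float(self(np.atleast_2d(multipliers))[0])


def fitness(
    log: PatientLog,
    params: GlycemiaParams,
    profile=None,
    absorption_params: AbsorptionParams | None = None,
    *,
    step: float = 1.0,
) -> float:
    """RMSE (mmol/l) of the full-window prediction with restarts vs CGMS."""
    space = ParameterSpace(names=(), reference=params)
    ev = FitnessEvaluator(log, space, absorption_params, step=step, profile=profile)
    return ev.scalar(np.zeros((1, 0)))


def ofat_sensitivity(
    log: PatientLog,
    multipliers: list[float],
    space: ParameterSpace,
    *,
    evaluator: FitnessEvaluator | None = None,
) -> pd.DataFrame:
    """One-factor-at-a-time sensitivity: fitness per (parameter, multiplier).

    Each parameter is swept over the multipliers while all others stay at
    their reference value; the multiplier-1.0 row is the shared baseline.
    """
    if 1.0 not in multipliers:
        raise ValueError("the multiplier list must include the baseline 1.0")
    ev = evaluator or FitnessEvaluator(log, space)
    rows = []
    for name in space.names:
        j = space.names.index(name)
        mat = np.ones((len(multipliers), space.n_params))
        mat[:, j] = multipliers
        values = ev(mat)
        for m, v in zip(multipliers, values):
            rows.append({"parameter": name, "multiplier": m, "fitness": v})
    return pd.DataFrame(rows)


def _grid_values(config: TrainingConfig) -> np.ndarray:
    k = np.arange(config.bf_steps) - (config.bf_steps - 1) // 2
    if config.bf_grid == "additive":
        return 1.0 + k * config.bf_step_size
    if config.bf_grid == "geometric":
        return (1.0 + config.bf_step_size) ** k
    raise ValueError(f"unknown grid semantics {config.bf_grid!r}")


def brute_force(
    log: PatientLog | None,
    space: ParameterSpace,
    config: TrainingConfig | None = None,
    *,
    evaluator: FitnessEvaluator | None = None,
    chunk: int = 128,
) -> FitResult:
    """Exhaustive grid search over the multiplier grid.

    With the default 7 steps of 20% the per-parameter grid is
    {0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6}; the number of fitness evaluations
    is exactly steps ** n_params.
    """
    config = config or TrainingConfig(method="brute_force")
    if config.bf_steps % 2 == 0:
        raise ValueError("bf_steps must be odd so the grid contains 1.0")
    ev = evaluator or FitnessEvaluator(log, space)
    values = _grid_values(config)
    grid = np.array(list(itertools.product(values, repeat=space.n_params)))
    best_fit = np.inf
    best_vec = np.ones(space.n_params)
    n_eval = 0
    for start in range(0, len(grid), chunk):
        block = grid[start : start + chunk]
        fits = ev(block)
        n_eval += len(block)
        i = int(np.argmin(fits))
        if fits[i] < best_fit:
            best_fit = float(fits[i])
            best_vec = block[i]
    return FitResult(
        multipliers=dict(zip(space.names, best_vec)),
        params=space.apply(best_vec),
        fitness=best_fit,
        n_evaluations=n_eval,
        method="brute_force",
    )


def ga_optimize(
    log: PatientLog | None,
    space: ParameterSpace,
    config: TrainingConfig,
    *,
    evaluator: FitnessEvaluator | None = None,
) -> FitResult:
    """Real-coded genetic algorithm over multiplier vectors within bounds.

    Tournament selection, blend (BLX-alpha) crossover, per-gene Gaussian
    mutation, elitism of one: the best-ever individual survives every
    generation and is the returned solution.  Identical seeds give
    identical results; out-of-bounds genes are clipped.
    """
    rng = np.random.default_rng(config.seed)
    ev = evaluator or FitnessEvaluator(log, space)
    k = space.n_params
    pop_n = config.population

    pop = rng.uniform(space.lower, space.upper, size=(pop_n, k))
    if config.include_reference:
        pop[0] = 1.0
    fits = ev(pop)
    best_i = int(np.argmin(fits))
    best_vec, best_fit = pop[best_i].copy(), float(fits[best_i])
    trace = [{"generation": 0, "best_fitness": best_fit}]

    for gen in range(1, config.generations + 1):
        # tournament selection
        parents = np.empty_like(pop)
        for i in range(pop_n):
            contenders = rng.integers(0, pop_n, size=config.tournament_size)
            parents[i] = pop[contenders[np.argmin(fits[contenders])]]
        # blend crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, pop_n - 1, 2):
            if rng.random() < config.cx_prob:
                a, b = parents[i], parents[i + 1]
                lo = np.minimum(a, b) - config.blend_alpha * np.abs(a - b)
                hi = np.maximum(a, b) + config.blend_alpha * np.abs(a - b)
                children[i] = rng.uniform(lo, hi)
                children[i + 1] = rng.uniform(lo, hi)
        # per-gene Gaussian mutation
        mutate = rng.random(children.shape) < config.mut_prob
        children = children + mutate * rng.normal(0.0, config.mut_sigma, children.shape)
        children = space.clip(children)
        # elitism: the best-ever individual replaces the first child
        children[0] = best_vec
        pop = children
        fits = ev(pop)
        best_i = int(np.argmin(fits))
        if fits[best_i] < best_fit:
            best_vec, best_fit = pop[best_i].copy(), float(fits[best_i])
        trace.append({"generation": gen, "best_fitness": best_fit})

    return FitResult(
        multipliers=dict(zip(space.names, best_vec)),
        params=space.apply(best_vec),
        fitness=best_fit,
        n_evaluations=ev.n_evaluations if evaluator is None else pop_n * (config.generations + 1),
        method=config.method if config.method.startswith("ga") else "ga",
        trace=trace,
    )


def nelder_mead_refine(
    log: PatientLog | None,
    space: ParameterSpace,
    start: FitResult | np.ndarray,
    max_iter: int = 100,
    *,
    evaluator: FitnessEvaluator | None = None,
) -> FitResult:
    """Downhill-simplex refinement of a previous result.

    The initial simplex spans +5% perturbations of the start vector; the
    returned fitness never exceeds the start fitness (monotone improvement
    contract).  Candidates are clipped to the multiplier bounds before
    evaluation.
    """
    ev = evaluator or FitnessEvaluator(log, space)
    x0 = start.vector(space.names) if isinstance(start, FitResult) else np.asarray(start, float)
    x0 = space.clip(x0)

    def objective(x: np.ndarray) -> float:
        return ev.scalar(space.clip(x))

    simplex = np.vstack([x0] + [x0 + np.eye(space.n_params)[j] * 0.05 * x0[j] for j in range(space.n_params)])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "initial_simplex": simplex, "xatol": 1e-6, "fatol": 1e-9},
    )
    best = space.clip(res.x)
    best_fit = float(res.fun)
    start_fit = start.fitness if isinstance(start, FitResult) else ev.scalar(x0)
    if start_fit < best_fit:  # guard against simplex collapse / stagnation
        best, best_fit = x0, start_fit
    return FitResult(
        multipliers=dict(zip(space.names, best)),
        params=space.apply(best),
        fitness=best_fit,
        n_evaluations=int(res.nfev),
        method="nelder_mead_refine",
    )


def train(
    log: PatientLog,
    space: ParameterSpace,
    config: TrainingConfig,
    *,
    refine: bool = False,
    evaluator: FitnessEvaluator | None = None,
) -> FitResult:
    """Run the configured identification method, optionally NM-refined."""
    if config.method == "brute_force":
        result = brute_force(log, space, config, evaluator=evaluator)
    elif config.method in ("ga_fast", "ga_slow", "ga"):
        result = ga_optimize(log, space, config, evaluator=evaluator)
    else:
        raise ValueError(f"unknown training method {config.method!r}")
    if refine:
        refined = nelder_mead_refine(
            log, space, result, max_iter=config.nm_max_iter, evaluator=evaluator
        )
        refined.n_evaluations += result.n_evaluations
        refined.method = result.method + "+nelder_mead"
        refined.trace = result.trace
        result = refined
    return result
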