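"""Weighted least-squares calibration with a hybrid global-local optimizer.

The cost is the maximum-likelihood criterion for Gaussian noise with known
variance,

    J(theta) = sum_e sum_o sum_s  (y_tilde - y(theta))^2 / sigma^2,

minimised over the free parameters inside box bounds.  Because such costs
are multimodal, the optimizer couples a scatter-search-style global phase
(Latin-hypercube diversification, reference-set recombination) with bounded
local Gauss-Newton refinement, searching in log10 space by default since
the rate constants span several orders of magnitude.  Everything is seeded
and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model_core import (ConfigurationError, DynamicModel, MeasurementSet,
                         ParameterSpace, SimulationError, predict_observables,
                         resting_state)

__all__ = ["CalibrationProblem", "OptimizerConfig", "CalibrationResult",
           "wls_cost", "calibrate"]

# Finite penalty for failed simulations: theta-dependent so the optimizer
# sees no flat plateau, large enough to dominate any data misfit.
def _penalty(theta: np.ndarray) -> float:
    return 1e10 * (1.0 + float(np.linalg.norm(theta)))


@dataclass
class CalibrationProblem:
    model: DynamicModel
    space: ParameterSpace
    datasets: list[MeasurementSet]
    free_names: list[str]
    log_scale: bool = True
    rtol: float = 1e-7
    atol: float = 1e-10
    base_theta: np.ndarray | None = None   # fixed-parameter values (default nominal)

    def __post_init__(self):
        declared = set(self.space.free_names)
        if not set(self.free_names) <= declared:
            raise ConfigurationError(
                "free subset must be within the declared free parameters")
        self.free_idx = self.space.indices(self.free_names)
        self.lower = self.space.lower[self.free_idx]
        self.upper = self.space.upper[self.free_idx]
        self._rest_guess = None
        self.n_data = int(sum(ms.design.n_points for ms in self.datasets))
        self._weights = {}   # (dataset index, observable) -> sqrt(w)
        for k, ms in enumerate(self.datasets):
            for o in ms.design.observables:
                sd = ms.sd[o]
                if (sd < 0).any():
                    raise ConfigurationError("negative measurement sd")
                # exact (sd = 0) in-silico points get unit weight
                self._weights[(k, o)] = 1.0 / np.where(sd > 0, sd, 1.0)

    def full_theta(self, free_values: np.ndarray) -> np.ndarray:
        return self.space.full_theta(free_values, self.free_names,
                                     base=self.base_theta)

    # -- weighted residuals ------------------------------------------------
    def residuals(self, free_values: np.ndarray) -> np.ndarray:
        theta = self.full_theta(free_values)
        try:
            if self.model.initial_condition_policy == "fixed":
                x0 = self.model.initial_state(theta)
            else:
                x0 = resting_state(self.model, theta,
                                   guess=self._rest_guess,
                                   rtol=self.rtol, atol=self.atol)
                self._rest_guess = x0
            out = []
            for k, ms in enumerate(self.datasets):
                pred = predict_observables(self.model, theta, ms.design,
                                           x0=x0, rtol=self.rtol,
                                           atol=self.atol)
                for o in ms.design.observables:
                    out.append((ms.values[o] - pred.values[o])
                               * self._weights[(k, o)])
            return np.concatenate(out)
        except SimulationError:
            return np.full(self.n_data,
                           np.sqrt(_penalty(theta) / self.n_data))

    def cost(self, free_values: np.ndarray) -> float:
        r = self.residuals(free_values)
        return float(r @ r)


def wls_cost(theta_free: np.ndarray, problem: CalibrationProblem) -> float:
    """J(theta): weighted least squares over every experiment, observable
    and sampling time; simulation failures yield a large finite penalty."""
    return problem.cost(np.asarray(theta_free, float))


@dataclass
class OptimizerConfig:
    budget: int = 10000           # total cost evaluations
    n_init: int | None = None     # global-phase LHS size (default 10*n_free)
    refset_size: int = 10
    local_every: int = 4          # recombination rounds between local polishes
    local_nfev: int = 400
    warm_start: np.ndarray | None = None   # skip global phase, polish from here
    xtol: float = 1e-10
    ftol: float = 1e-10

    @classmethod
    def warm(cls, start: np.ndarray, budget: int = 400) -> "OptimizerConfig":
        """Profile for Monte-Carlo replicate fits: local refinement only,
        started from a reference estimate."""
        return cls(budget=budget, warm_start=np.asarray(start, float),
                   local_nfev=budget)


@dataclass
class CalibrationResult:
    theta_hat: np.ndarray         # free-parameter estimates, native units
    cost: float
    trace: list[tuple[int, float]]   # (n_evaluations, best J so far)
    status: str
    seed: int | None
    n_evaluations: int
    free_names: list[str] = field(default_factory=list)


class _Counter:
    """Wraps the cost in z-space, counting evaluations and tracking the best."""

    def __init__(self, problem: CalibrationProblem):
        self.problem = problem
        lo, up = problem.lower, problem.upper
        if problem.log_scale:
            if (lo <= 0).any():
                raise ConfigurationError("log-scale search needs positive bounds")
            self.a, self.b = np.log10(lo), np.log10(up)
            self.to_theta = lambda z: 10 ** (self.a + z * (self.b - self.a))
            self.to_z = lambda th: (np.log10(th) - self.a) / (self.b - self.a)
        else:
            self.a, self.b = lo, up
            self.to_theta = lambda z: self.a + z * (self.b - self.a)
            self.to_z = lambda th: (th - self.a) / (self.b - self.a)
        self.n = 0
        self.best = (np.inf, None)
        self.trace: list[tuple[int, float]] = []

    def residuals_z(self, z):
        r = self.problem.residuals(self.to_theta(np.clip(z, 0, 1)))
        self._register(float(r @ r), z)
        return r

    def cost_z(self, z):
        J = self.problem.cost(self.to_theta(np.clip(z, 0, 1)))
        self._register(J, z)
        return J

    def _register(self, J, z):
        self.n += 1
        if J < self.best[0]:
            self.best = (J, np.clip(z, 0, 1).copy())
            self.trace.append((self.n, J))


def _local_polish(counter: _Counter, z0, max_nfev, cfg):
    try:
        least_squares(counter.residuals_z, np.clip(z0, 0, 1),
                      bounds=(0.0, 1.0), method="trf", diff_step=1e-4,
                      xtol=cfg.xtol, ftol=cfg.ftol, gtol=1e-12,
                      max_nfev=max(max_nfev, 2))
    except Exception:
        pass  # keep the best point seen so far


def calibrate(problem: CalibrationProblem, config: OptimizerConfig | None = None,
              seed: int = 0) -> CalibrationResult:
    """Hybrid global-local estimation: seeded LHS diversification feeding a
    reference set that is recombined scatter-search style, with periodic
    bounded Gauss-Newton polish of the incumbent; `warm_start` skips the
    global phase (Monte-Carlo replicate profile)."""
    cfg = config or OptimizerConfig()
    counter = _Counter(problem)
    f = len(problem.free_names)
    rng = np.random.default_rng(seed)

    if cfg.warm_start is not None:
        z0 = np.clip(counter.to_z(np.asarray(cfg.warm_start, float)), 0, 1)
        counter.cost_z(z0)
        _local_polish(counter, z0, min(cfg.local_nfev, cfg.budget), cfg)
        return _result(counter, problem, seed)

    n_init = cfg.n_init or min(10 * f, max(cfg.budget // 4, 4))
    sampler = qmc.LatinHypercube(d=f, seed=int(rng.integers(2 ** 31)))
    pop = sampler.random(n_init)
    costs = np.array([counter.cost_z(z) for z in pop])

    b = min(cfg.refset_size, n_init)
    order = np.argsort(costs)
    ref = [pop[i].copy() for i in order[: b // 2]]
    refJ = [costs[i] for i in order[: b // 2]]
    # diverse half: greedy max-min distance among the remainder
    rest = [pop[i] for i in order[b // 2:]]
    restJ = [costs[i] for i in order[b // 2:]]
    while len(ref) < b and rest:
        dists = [min(np.linalg.norm(r - q) for q in ref) for r in rest]
        k = int(np.argmax(dists))
        ref.append(rest.pop(k).copy())
        refJ.append(restJ.pop(k))

    rounds = 0
    while counter.n < cfg.budget:
        rounds += 1
        order = np.argsort(refJ)
        for ii in range(len(ref)):
            for jj in range(ii + 1, len(ref)):
                if counter.n >= cfg.budget:
                    break
                zi, zj = ref[order[ii]], ref[order[jj]]
                r = rng.uniform(-0.3, 1.3, f)
                child = np.clip(zi + r * (zj - zi), 0, 1)
                Jc = counter.cost_z(child)
                worst = int(np.argmax(refJ))
                if Jc < refJ[worst] and \
                        min(np.linalg.norm(child - q) for q in ref) > 1e-9:
                    ref[worst] = child
                    refJ[worst] = Jc
        if rounds % cfg.local_every == 0 and counter.n < cfg.budget:
            nf = min(cfg.local_nfev, cfg.budget - counter.n)
            _local_polish(counter, counter.best[1], nf, cfg)
            best = int(np.argmax(refJ))
            if counter.best[0] < refJ[best]:
                ref[best] = counter.best[1].copy()
                refJ[best] = counter.best[0]
    if counter.best[1] is not None:
        _local_polish(counter, counter.best[1], cfg.local_nfev, cfg)
    return _result(counter, problem, seed)


def _result(counter: _Counter, problem: CalibrationProblem, seed
            ) -> CalibrationResult:
    J, z = counter.best
    if z is None or not np.isfinite(J):
        raise SimulationError("no successful cost evaluation within budget")
    status = "ok" if J < 1e9 else "all-evaluations-penalised"
    return CalibrationResult(theta_hat=counter.to_theta(z), cost=J,
                             trace=list(counter.trace), status=status,
                             seed=seed, n_evaluations=counter.n,
                             free_names=list(problem.free_names))
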