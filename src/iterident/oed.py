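"""Fisher-information-based optimal experimental design.

For Gaussian noise the information a scheme carries about the parameters is

    F = sum_{e,o,s}  (1/sigma_eos^2)  (dy/dtheta) (dy/dtheta)^T ,

evaluated at a reference parameter vector mu (the current best estimate).
Designs are scored by D-optimality (det F) or E-optimality (smallest
eigenvalue of F); new experiments are designed *sequentially*, maximising
the criterion of F_prior + F(design) so that each experiment complements
the information already collected.  Decision variables are the pulse switch
times of the binary stimulus (up to a configured number of pulses), the
experiment duration and the sampling times; a seeded stochastic global
search (differential evolution) with constraint repair does the
maximisation, since the E-criterion is non-smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .model_core import (ConfigurationError, DynamicModel, ExperimentDesign,
                         NoiseSpec, SimulationError, StimulusProfile)
from .sensitivity import forward_sensitivities

__all__ = ["FIMatrix", "DesignConstraints", "OEDProblem", "OEDResult",
           "fisher_information", "design_criterion", "optimize_design",
           "predicted_uncertainty_from_fim"]


@dataclass
class FIMatrix:
    matrix: np.ndarray
    free_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        M = np.asarray(self.matrix, float)
        if not np.allclose(M, M.T, atol=1e-8 * (np.abs(M).max() + 1e-300)):
            raise ConfigurationError("Fisher matrix must be symmetric")
        self.matrix = 0.5 * (M + M.T)

    def __add__(self, other: "FIMatrix") -> "FIMatrix":
        if self.free_names != other.free_names:
            raise ConfigurationError("incompatible parameter sets")
        return FIMatrix(self.matrix + other.matrix, list(self.free_names),
                        {"sum": [self.provenance, other.provenance]})


def fisher_information(model: DynamicModel, mu: np.ndarray,
                       designs: list[ExperimentDesign] | ExperimentDesign,
                       free_names: list[str],
                       noise_spec: NoiseSpec | None = None,
                       x0: np.ndarray | None = None,
                       engine: str = "ode", dense_dt: float = 1.0,
                       rtol: float = 1e-7, atol: float = 1e-10) -> FIMatrix:
    """F at the reference mu; weights 1/sigma^2 with sigma from the noise
    model applied to the predicted signals.  Additive over experiments."""
    if isinstance(designs, ExperimentDesign):
        designs = [designs]
    noise_spec = noise_spec or NoiseSpec()
    mu = np.asarray(mu, float)
    f = len(free_names)
    F = np.zeros((f, f))
    if x0 is None:
        x0 = model.x0_for(mu, rtol=rtol, atol=atol)
    for d in designs:
        sens = forward_sensitivities(model, mu, d, free_names, x0=x0,
                                     rtol=rtol, atol=atol, engine=engine,
                                     dense_dt=dense_dt)
        for o in d.observables:
            sigma = noise_spec.sigma(sens.y[o])
            W = sens.dydtheta[o] / sigma[:, None]
            F += W.T @ W
    return FIMatrix(F, list(free_names),
                    {"mu": mu.tolist(), "noise_rel": noise_spec.rel,
                     "designs": [d.name for d in designs]})


def design_criterion(F: FIMatrix | np.ndarray, kind: str = "E") -> float:
    M = F.matrix if isinstance(F, FIMatrix) else np.asarray(F, float)
    if kind == "D":
        return float(max(np.linalg.det(M), 0.0))
    if kind == "E":
        return float(max(np.linalg.eigvalsh(M)[0], 0.0))
    raise ConfigurationError(f"unknown criterion {kind!r}")


def predicted_uncertainty_from_fim(F: FIMatrix) -> dict:
    """Cramer-Rao bound: sd = sqrt(diag F^-1) and the implied pairwise
    correlations; singular information is flagged and handled with the
    pseudo-inverse (infinite sd along null directions)."""
    M = F.matrix
    evals = np.linalg.eigvalsh(M)
    singular = evals[0] <= 1e-12 * max(evals[-1], 1e-300)
    cov = np.linalg.pinv(M, hermitian=True)
    var = np.diag(cov).copy()
    if singular:
        _, _, Vt = np.linalg.svd(M)
        null = Vt[np.abs(evals) <= 1e-12 * max(evals[-1], 1e-300)]
        onnull = (np.abs(Vt[-1]) > 1e-8)
        var = np.where(onnull, np.inf, var)
    sd = np.sqrt(np.maximum(var, 0.0))
    denom = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
    corr = cov / denom[:, None] / denom[None, :]
    np.fill_diagonal(corr, 1.0)
    return {"sd": sd, "correlation": corr, "singular": bool(singular),
            "names": list(F.free_names)}


@dataclass
class DesignConstraints:
    max_pulses: int = 2
    max_samples: int = 15
    duration_bounds: tuple[float, float] = (120.0, 480.0)
    min_pulse_width: float = 1.0
    min_sample_spacing: float = 1.0
    optimize_duration: bool = True

    def __post_init__(self):
        lo, hi = self.duration_bounds
        if not (0 < lo < hi):
            raise ConfigurationError("invalid duration bounds")
        if self.max_samples * self.min_sample_spacing > hi:
            raise ConfigurationError("sampling constraints infeasible")
        if 2 * self.max_pulses * self.min_pulse_width > hi:
            raise ConfigurationError("pulse constraints infeasible")


@dataclass
class OEDProblem:
    model: DynamicModel
    mu: np.ndarray
    free_names: list[str]
    observables: list[str]
    prior_fim: FIMatrix | None = None
    criterion: str = "E"
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)


@dataclass
class OEDResult:
    design: ExperimentDesign
    criterion_value: float
    prior_criterion: float
    flat_objective: bool
    predicted: dict
    trace: list[tuple[int, float]]
    seed: int
    n_evaluations: int


def _decode(v: np.ndarray, cons: DesignConstraints, name: str,
            noise: NoiseSpec, observables: list[str]) -> ExperimentDesign:
    """Map the unit cube to a feasible design with ordering/min-spacing
    repair: [duration | 2*max_pulses switch fractions | max_samples gaps]."""
    k = 0
    lo, hi = cons.duration_bounds
    if cons.optimize_duration:
        duration = lo + v[0] * (hi - lo)
        k = 1
    else:
        duration = hi
    npulse_vars = 2 * cons.max_pulses
    sw = np.sort(v[k:k + npulse_vars]) * duration
    # repair: enforce minimum pulse width by collapsing degenerate pulses
    switches = []
    for t in sw:
        if not switches or t - switches[-1] >= cons.min_pulse_width:
            switches.append(float(min(t, duration)))
    if len(switches) % 2 == 1:
        # stimulus left on: close the pulse at the horizon, or drop the
        # dangling switch when that would violate the minimum width
        if duration - switches[-1] >= cons.min_pulse_width:
            switches = switches + [duration]
        else:
            switches = switches[:-1]
    k += npulse_vars
    gaps = np.maximum(v[k:k + cons.max_samples], 1e-6)
    tsamp = np.cumsum(gaps)
    tsamp = tsamp / tsamp[-1] * duration
    # min-spacing repair via cumulative maximum, then clip from the top
    for i in range(1, tsamp.size):
        tsamp[i] = max(tsamp[i], tsamp[i - 1] + cons.min_sample_spacing)
    over = tsamp[-1] - duration
    if over > 0:
        tsamp = tsamp - over
        tsamp = np.maximum.accumulate(
            np.maximum(tsamp, cons.min_sample_spacing))
        for i in range(1, tsamp.size):
            tsamp[i] = max(tsamp[i], tsamp[i - 1] + cons.min_sample_spacing)
        tsamp = np.minimum(tsamp, duration)
        tsamp = np.unique(tsamp)
    stim = StimulusProfile(switches, duration, max_pulses=cons.max_pulses)
    return ExperimentDesign(name=name, stimulus=stim,
                            observables=list(observables),
                            sampling_times={o: tsamp.copy()
                                            for o in observables},
                            noise=noise)


def optimize_design(problem: OEDProblem, budget: int = 600, popsize: int = 16,
                    seed: int = 0, engine: str = "magnus",
                    dense_dt: float = 0.5, name: str = "designed"
                    ) -> OEDResult:
    """Maximise criterion(F_prior + F(design)) over pulse switch times,
    duration and sampling times with a seeded differential-evolution search
    in the encoded unit cube."""
    cons = problem.constraints
    f = len(problem.free_names)
    prior = problem.prior_fim.matrix if problem.prior_fim is not None \
        else np.zeros((f, f))
    prior_crit = design_criterion(FIMatrix(prior, list(problem.free_names)),
                                  problem.criterion)
    mu = np.asarray(problem.mu, float)
    x0 = problem.model.x0_for(mu)
    dim = (1 if cons.optimize_duration else 0) + 2 * cons.max_pulses \
        + cons.max_samples
    count = [0]
    trace: list[tuple[int, float]] = []
    best = [-np.inf]

    def objective(v):
        count[0] += 1
        try:
            design = _decode(v, cons, name, problem.noise_spec,
                             problem.observables)
            F = fisher_information(problem.model, mu, design,
                                   problem.free_names,
                                   noise_spec=problem.noise_spec, x0=x0,
                                   engine=engine, dense_dt=dense_dt)
            val = design_criterion(FIMatrix(prior + F.matrix,
                                            list(problem.free_names)),
                                   problem.criterion)
        except (SimulationError, ConfigurationError):
            return 1e30
        if val > best[0]:
            best[0] = val
            trace.append((count[0], val))
        return -val

    from scipy.stats import qmc
    pop = int(min(max(popsize, 8), max(budget // 4, 8)))
    maxiter = max(budget // pop - 1, 1)
    init = qmc.LatinHypercube(d=dim, seed=seed).random(pop)
    res = differential_evolution(
        objective, bounds=[(0.0, 1.0)] * dim, seed=seed, init=init,
        maxiter=maxiter, polish=False, tol=0,
        mutation=(0.4, 1.0), recombination=0.8, updating="deferred",
        workers=1)
    vbest = res.x
    design = _decode(vbest, cons, name, problem.noise_spec,
                     problem.observables)
    F = fisher_information(problem.model, mu, design, problem.free_names,
                           noise_spec=problem.noise_spec, x0=x0,
                           engine=engine, dense_dt=dense_dt)
    total = FIMatrix(prior + F.matrix, list(problem.free_names))
    crit = design_criterion(total, problem.criterion)
    flat = prior_crit > 0 and (crit - prior_crit) < 1e-3 * prior_crit
    return OEDResult(design=design, criterion_value=crit,
                     prior_criterion=prior_crit, flat_objective=bool(flat),
                     predicted=predicted_uncertainty_from_fim(total),
                     trace=trace, seed=seed, n_evaluations=count[0])
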