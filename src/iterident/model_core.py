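"""Core representation of control-affine dynamic models and in-silico data.

A model is a set of nonlinear ODEs

    dx/dt = f(x, theta) + sum_i u_i(t) * g_i(x, theta),

with piecewise-constant binary stimuli u(t), linear discrete-time observables
y = C x sampled at given times, and heteroscedastic Gaussian measurement
noise.  Models are declared symbolically (sympy expression strings) so the
same definition serves numerical simulation, forward sensitivities and
structural identifiability analysis; built-in models may additionally supply
hand-optimised numerical kernels.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp
import yaml
from scipy.integrate import odeint

__all__ = [
    "ConfigurationError",
    "SimulationError",
    "SymbolicModel",
    "DynamicModel",
    "ParameterSpace",
    "StimulusProfile",
    "NoiseSpec",
    "ExperimentDesign",
    "MeasurementSet",
    "model_from_config",
    "resting_state",
    "simulate",
    "predict_observables",
    "generate_noisy_replicate",
    "measurements_to_frame",
    "measurements_from_frame",
    "write_measurements_csv",
    "read_measurements_csv",
    "design_to_dict",
    "design_from_dict",
]


class ConfigurationError(ValueError):
    """Invalid model, design or noise configuration."""


class SimulationError(RuntimeError):
    """Integrator/root-finder failure; carries the parameter vector so that
    optimisation layers can penalise instead of crash."""

    def __init__(self, message: str, theta: np.ndarray | None = None):
        super().__init__(message)
        self.theta = None if theta is None else np.asarray(theta, float).copy()


# ---------------------------------------------------------------------------
# Symbolic + numeric model containers
# ---------------------------------------------------------------------------

@dataclass
class SymbolicModel:
    """Sympy-level description: drift, stimulus fields and observables."""

    x: list[sp.Symbol]
    theta: list[sp.Symbol]
    u: list[sp.Symbol]
    drift: list[sp.Expr]              # f(x, theta)
    fields: list[list[sp.Expr]]       # g_i(x, theta), one list per stimulus
    observables: dict[str, sp.Expr]   # linear combinations of states
    initial: list[sp.Expr]            # seed state, expressions in theta

    def rhs_exprs(self) -> list[sp.Expr]:
        out = []
        for k in range(len(self.x)):
            e = self.drift[k]
            for ui, g in zip(self.u, self.fields):
                e = e + ui * g[k]
            out.append(sp.expand(e))
        return out


@dataclass
class DynamicModel:
    name: str
    state_names: list[str]
    param_names: list[str]
    control_names: list[str]
    observable_defs: dict[str, dict[str, float]]  # name -> {state: coeff}
    rhs: Callable            # rhs(x, u, theta) -> dx
    drift: Callable          # drift(x, theta) -> f
    control_fields: Callable  # (x, theta) -> (n_controls, n_states)
    jac_x: Callable          # (x, u, theta) -> (n, n)
    jac_theta: Callable      # (x, u, theta) -> (n, n_params)
    symbolic: SymbolicModel | None = None
    initial_condition_policy: str = "resting"   # "resting" | "fixed"
    seed_state: Callable | None = None          # theta -> x_seed
    fixed_initial: np.ndarray | None = None
    conserved: Callable | None = None  # theta -> (n_c, n_states) linear laws

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    def observation_matrix(self, observables: Sequence[str]) -> np.ndarray:
        """Rows of the linear observation map for the named observables."""
        C = np.zeros((len(observables), self.n_states))
        for i, name in enumerate(observables):
            if name not in self.observable_defs:
                raise ConfigurationError(f"unknown observable {name!r}")
            for sname, coeff in self.observable_defs[name].items():
                C[i, self.state_index(sname)] = coeff
        return C

    def initial_state(self, theta: np.ndarray) -> np.ndarray:
        """Seed state for the resting-state computation, or — under the
        "fixed" policy — the actual x(0), which may depend on theta."""
        if self.seed_state is None:
            raise ConfigurationError("no seed state defined")
        return np.asarray(self.seed_state(np.asarray(theta, float)), float)

    def x0_for(self, theta: np.ndarray, **resting_kw) -> np.ndarray:
        """x(0) according to the initial-condition policy."""
        if self.initial_condition_policy == "fixed":
            return self.initial_state(theta)
        return resting_state(self, theta, **resting_kw)


@dataclass
class ParameterSpace:
    names: list[str]
    nominal: np.ndarray
    free_mask: np.ndarray        # bool, which parameters are estimated
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.nominal = np.asarray(self.nominal, float)
        self.free_mask = np.asarray(self.free_mask, bool)
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        bad = self.free_mask & ~(self.lower < self.upper)
        if bad.any():
            raise ConfigurationError(
                f"free parameters need lower < upper: {self.names_at(bad)}")
        inside = (self.nominal >= self.lower) & (self.nominal <= self.upper)
        if not inside[self.free_mask].all():
            raise ConfigurationError("nominal outside bounds for a free parameter")

    def names_at(self, mask) -> list[str]:
        return [n for n, m in zip(self.names, mask) if m]

    @property
    def free_names(self) -> list[str]:
        return self.names_at(self.free_mask)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], int)

    def full_theta(self, free_values: np.ndarray,
                   free_names: Sequence[str] | None = None,
                   base: np.ndarray | None = None) -> np.ndarray:
        """Insert free values into the nominal (or given base) vector."""
        theta = (self.nominal if base is None else np.asarray(base, float)).copy()
        names = self.free_names if free_names is None else list(free_names)
        theta[self.indices(names)] = free_values
        return theta

    def with_free(self, names: Sequence[str]) -> "ParameterSpace":
        """Partition: keep only `names` free, everything else fixed (Eq.-16
        style theta_kappa selection)."""
        unknown = set(names) - set(self.names)
        if unknown:
            raise ConfigurationError(f"unknown parameters {sorted(unknown)}")
        mask = np.array([n in set(names) for n in self.names])
        return ParameterSpace(self.names, self.nominal.copy(), mask,
                              self.lower.copy(), self.upper.copy())

    def scaled_bounds(self, scale: float) -> "ParameterSpace":
        """Reference-centred box (nominal/scale, nominal*scale) for free params."""
        lo, up = self.lower.copy(), self.upper.copy()
        lo[self.free_mask] = self.nominal[self.free_mask] / scale
        up[self.free_mask] = self.nominal[self.free_mask] * scale
        return ParameterSpace(self.names, self.nominal.copy(),
                              self.free_mask.copy(), lo, up)


# ---------------------------------------------------------------------------
# Stimuli, designs, measurements
# ---------------------------------------------------------------------------

@dataclass
class StimulusProfile:
    """Binary stimulus T_R(t): 0 before the first switch time, toggling at
    each switch.  A persistent stimulus is ``switch_times=[0.0]``."""

    switch_times: list[float]
    duration: float
    max_pulses: int = 8

    def __post_init__(self):
        st = [float(t) for t in self.switch_times]
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ConfigurationError("switch times must be strictly increasing")
        if st and (st[0] < 0 or st[-1] > self.duration):
            raise ConfigurationError("switch times outside [0, duration]")
        n_pulses = (len(st) + 1) // 2
        if n_pulses > self.max_pulses:
            raise ConfigurationError(f"more than {self.max_pulses} pulses")
        self.switch_times = st

    @property
    def kind(self) -> str:
        if len(self.switch_times) == 1 and self.switch_times[0] == 0.0:
            return "persistent"
        return "pulse-train" if self.switch_times else "off"

    def value(self, t: float) -> float:
        return float(sum(1 for s in self.switch_times if s <= t) % 2)

    def segments(self) -> list[tuple[float, float, float]]:
        """(t_start, t_end, u) pieces covering [0, duration]."""
        edges = [0.0] + [s for s in self.switch_times if 0.0 < s < self.duration] \
            + [self.duration]
        out = []
        for a, b in zip(edges, edges[1:]):
            out.append((a, b, self.value(a)))
        return out

    @classmethod
    def persistent(cls, duration: float) -> "StimulusProfile":
        return cls([0.0], duration)

    @classmethod
    def pulse(cls, on: float, off: float, duration: float) -> "StimulusProfile":
        return cls([on, off], duration)


@dataclass
class NoiseSpec:
    """Heteroscedastic Gaussian noise: sd = rel*|signal| + floor."""

    rel: float = 0.10
    floor: float = 1e-6

    def __post_init__(self):
        if self.rel < 0 or self.floor < 0:
            raise ConfigurationError("noise rel and floor must be non-negative")

    def sigma(self, y: np.ndarray) -> np.ndarray:
        return self.rel * np.abs(y) + self.floor


@dataclass
class ExperimentDesign:
    name: str
    stimulus: StimulusProfile
    observables: list[str]
    sampling_times: dict[str, np.ndarray]   # observable -> sorted times (min)
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self):
        for o in self.observables:
            if o not in self.sampling_times:
                raise ConfigurationError(f"no sampling times for {o!r}")
            ts = np.asarray(self.sampling_times[o], float)
            if ts.ndim != 1 or (np.diff(ts) <= 0).any():
                raise ConfigurationError("sampling times must be strictly increasing")
            if ts.size and (ts[0] < 0 or ts[-1] > self.stimulus.duration):
                raise ConfigurationError("sampling times outside [0, duration]")
            self.sampling_times[o] = ts

    def union_times(self) -> np.ndarray:
        allt = np.concatenate([self.sampling_times[o] for o in self.observables])
        return np.unique(allt)

    @property
    def n_points(self) -> int:
        return int(sum(self.sampling_times[o].size for o in self.observables))


@dataclass
class MeasurementSet:
    design: ExperimentDesign
    values: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for o in self.design.observables:
            v = np.asarray(self.values[o], float)
            s = np.asarray(self.sd[o], float)
            if v.shape != self.design.sampling_times[o].shape or s.shape != v.shape:
                raise ConfigurationError(f"shape mismatch for observable {o!r}")
            # sd == 0 is allowed only for exact (noise-free) in-silico data
            if (s < 0).any():
                raise ConfigurationError("sd must be non-negative")
            self.values[o], self.sd[o] = v, s


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_ODE_MXSTEP = 200000


def _integrate_segment(model, x0, u, theta, t_eval, rtol, atol):
    uvec = np.atleast_1d(np.asarray(u, float))

    def f(x, t):
        return model.rhs(x, uvec, theta)

    def jac(x, t):
        return model.jac_x(x, uvec, theta)

    out, info = odeint(f, x0, t_eval, Dfun=jac, rtol=rtol, atol=atol,
                       mxstep=_ODE_MXSTEP, full_output=True)
    if info["message"] != "Integration successful.":
        raise SimulationError(f"ODE integration failed: {info['message']}", theta)
    if not np.isfinite(out).all():
        raise SimulationError("non-finite states in trajectory", theta)
    return out


def simulate(model: DynamicModel, theta: np.ndarray, stimulus: StimulusProfile,
             times: np.ndarray, x0: np.ndarray | None = None,
             rtol: float = 1e-8, atol: float = 1e-12) -> np.ndarray:
    """Integrate the model under a piecewise-constant stimulus and return the
    states at `times`.  Integration restarts at every stimulus switch so the
    stiff solver never steps across a discontinuity."""
    theta = np.asarray(theta, float)
    times = np.asarray(times, float)
    if x0 is None:
        x0 = model.x0_for(theta, rtol=rtol, atol=atol)
    out = np.empty((times.size, model.n_states))
    filled = np.zeros(times.size, bool)
    if times.size and times.min() < 0:
        raise ConfigurationError("negative sampling time")
    x = np.asarray(x0, float).copy()
    at0 = times == 0.0
    out[at0] = x
    filled |= at0
    for a, b, u in stimulus.segments():
        sel = (times > a) & (times <= b)
        seg_times = times[sel]
        t_eval = np.concatenate([[a], seg_times, [b]])
        t_eval = np.unique(t_eval)
        traj = _integrate_segment(model, x, u, theta, t_eval, rtol, atol)
        # map back the requested times (t_eval is unique-sorted)
        idx = np.searchsorted(t_eval, seg_times)
        out[sel] = traj[idx]
        filled |= sel
        x = traj[-1]
    if not filled.all():
        raise ConfigurationError("sampling times beyond the stimulus duration")
    return out


def resting_state(model: DynamicModel, theta: np.ndarray,
                  guess: np.ndarray | None = None, t_rest: float = 1e4,
                  tol: float = 1e-10, rtol: float = 1e-8, atol: float = 1e-12,
                  max_newton: int = 25) -> np.ndarray:
    """Unstimulated steady state (u = 0): long-horizon integration from the
    model's seed state followed by a Newton polish.

    When `guess` is given the integration phase is skipped and the Newton
    iteration starts there (fast path for repeated calls during calibration);
    the result is validated and the slow path is used as fallback.  Linear
    conservation laws (e.g. the total NF-kB pool) are appended to the Newton
    system so the polish stays on the correct invariant manifold.
    """
    theta = np.asarray(theta, float)
    u0 = np.zeros(max(1, len(model.control_names)))

    def polish(x):
        x = x.copy()
        cons = model.conserved(theta) if model.conserved is not None else None
        target = cons @ x if cons is not None else None
        for _ in range(max_newton):
            r = model.rhs(x, u0, theta)
            if np.linalg.norm(r) < tol:
                return x, True
            J = model.jac_x(x, u0, theta)
            if cons is not None:
                A = np.vstack([J, cons])
                b = np.concatenate([-r, target - cons @ x])
            else:
                A, b = J, -r
            try:
                dx = np.linalg.lstsq(A, b, rcond=None)[0]
            except np.linalg.LinAlgError:
                return x, False
            x = x + dx
            if not np.isfinite(x).all():
                return x, False
        return x, np.linalg.norm(model.rhs(x, u0, theta)) < tol

    if guess is not None:
        x, ok = polish(np.asarray(guess, float))
        if ok and x.min() > -1e-9:
            return np.maximum(x, 0.0) if x.min() < 0 else x

    x0 = model.initial_state(theta)
    off = StimulusProfile([], t_rest)
    traj = simulate(model, theta, off, np.array([t_rest]), x0=x0,
                    rtol=rtol, atol=atol)
    x, ok = polish(traj[-1])
    if not ok or x.min() < -1e-8:
        res = np.linalg.norm(model.rhs(x, u0, theta))
        raise SimulationError(
            f"resting state did not converge (|rhs| = {res:.3e}); the "
            "unstimulated dynamics may be oscillatory or divergent", theta)
    return np.maximum(x, 0.0) if x.min() < 0 else x


def predict_observables(model: DynamicModel, theta: np.ndarray,
                        design: ExperimentDesign,
                        x0: np.ndarray | None = None, rtol: float = 1e-8,
                        atol: float = 1e-12) -> MeasurementSet:
    """Noiseless model predictions y = g(x(t_s)) for every observable of the
    design; stored sd is the noise model evaluated on the true signal."""
    tgrid = design.union_times()
    X = simulate(model, theta, design.stimulus, tgrid, x0=x0,
                 rtol=rtol, atol=atol)
    C = model.observation_matrix(design.observables)
    Y = X @ C.T
    values, sd = {}, {}
    for i, o in enumerate(design.observables):
        idx = np.searchsorted(tgrid, design.sampling_times[o])
        y = Y[idx, i]
        values[o] = y
        sd[o] = design.noise.sigma(y)
    return MeasurementSet(design, values, sd,
                          provenance={"kind": "prediction",
                                      "theta": theta.tolist()})


def generate_noisy_replicate(noiseless: MeasurementSet, noise_spec: NoiseSpec,
                             seed) -> MeasurementSet:
    """One in-silico experimental replicate: value = truth + N(0, sigma^2)
    with sigma = rel*|truth| + floor; reproducible from `seed` (an int or a
    numpy SeedSequence/Generator)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    values, sd = {}, {}
    for o in noiseless.design.observables:
        truth = noiseless.values[o]
        if not np.isfinite(truth).all():
            raise ConfigurationError("non-finite noiseless values")
        sigma = noise_spec.sigma(truth)
        values[o] = truth + rng.normal(0.0, 1.0, truth.shape) * sigma
        sd[o] = sigma
    prov = dict(noiseless.provenance)
    prov.update({"kind": "in-silico", "noise_rel": noise_spec.rel,
                 "noise_floor": noise_spec.floor})
    return MeasurementSet(noiseless.design, values, sd, provenance=prov)


# ---------------------------------------------------------------------------
# Tabular / file interfaces
# ---------------------------------------------------------------------------

def measurements_to_frame(sets: Sequence[MeasurementSet]) -> pd.DataFrame:
    rows = []
    for ms in sets:
        for o in ms.design.observables:
            for t, v, s in zip(ms.design.sampling_times[o], ms.values[o],
                               ms.sd[o]):
                rows.append((ms.design.name, o, t, v, s))
    return pd.DataFrame(rows, columns=["experiment", "observable", "time_min",
                                       "value", "sd"])


def measurements_from_frame(df: pd.DataFrame,
                            designs: Mapping[str, ExperimentDesign]
                            ) -> list[MeasurementSet]:
    out = []
    for ename, sub in df.groupby("experiment", sort=False):
        design = designs[ename]
        values, sd = {}, {}
        for o in design.observables:
            so = sub[sub.observable == o].sort_values("time_min")
            ts = so.time_min.to_numpy()
            if not np.allclose(ts, design.sampling_times[o]):
                raise ConfigurationError(
                    f"times in table do not match design {ename!r}/{o!r}")
            values[o] = so.value.to_numpy()
            sd[o] = so.sd.to_numpy()
        out.append(MeasurementSet(design, values, sd,
                                  provenance={"kind": "external"}))
    return out


def write_measurements_csv(path, sets: Sequence[MeasurementSet]) -> None:
    df = measurements_to_frame(sets)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_measurements_csv(path, designs) -> list[MeasurementSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    return measurements_from_frame(df, designs)


def design_to_dict(design: ExperimentDesign) -> dict:
    return {
        "name": design.name,
        "stimulus": {"switch_times": list(design.stimulus.switch_times),
                     "duration": design.stimulus.duration},
        "observables": list(design.observables),
        "sampling_times": {o: design.sampling_times[o].tolist()
                           for o in design.observables},
        "noise": {"rel": design.noise.rel, "floor": design.noise.floor},
    }


def design_from_dict(d: dict) -> ExperimentDesign:
    return ExperimentDesign(
        name=d["name"],
        stimulus=StimulusProfile(d["stimulus"]["switch_times"],
                                 d["stimulus"]["duration"]),
        observables=list(d["observables"]),
        sampling_times={o: np.asarray(v, float)
                        for o, v in d["sampling_times"].items()},
        noise=NoiseSpec(**d.get("noise", {})),
    )


# ---------------------------------------------------------------------------
# Declarative model configuration
# ---------------------------------------------------------------------------

def _lambdify(args, exprs, shape=None):
    f = sp.lambdify(args, exprs, modules="numpy")

    def wrapped(*a):
        out = np.asarray(f(*a))   # dtype preserved (complex-step capable)
        if out.dtype == object:
            out = out.astype(float)
        return out if shape is None else out.reshape(shape)

    return wrapped


def model_from_config(config: dict | str, name: str | None = None
                      ) -> tuple[DynamicModel, ParameterSpace]:
    """Build a model + parameter space from a declarative description.

    Schema::

        states: [name, ...]
        controls: [name, ...]                  # optional
        params:  [{name, value, free?, lower?, upper?}, ...]
        rhs:     {state: "sympy expression", ...}
        observables: {name: {state: coeff}, ...}
        initial: {policy: resting|fixed, seed: {state: "expr in params"}}
        bounds_scale: 10                       # default free-param box
        time_scale: 1.0                        # rhs multiplier; e.g. 60 when
                                               # rate constants are per second
                                               # but time is tracked in minutes

    The right-hand side must be control-affine (linear in every control);
    this is verified symbolically.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    state_names = list(config["states"])
    control_names = list(config.get("controls", []))
    pitems = config["params"]
    param_names = [p["name"] for p in pitems]
    nominal = np.array([float(p["value"]) for p in pitems])
    free_mask = np.array([bool(p.get("free", False)) for p in pitems])
    scale = float(config.get("bounds_scale", 10.0))
    lower = np.where(free_mask, nominal / scale, nominal)
    upper = np.where(free_mask, nominal * scale, nominal)
    for i, p in enumerate(pitems):
        if "lower" in p:
            lower[i] = float(p["lower"])
        if "upper" in p:
            upper[i] = float(p["upper"])

    x = [sp.Symbol(s, real=True) for s in state_names]
    th = [sp.Symbol(p, real=True) for p in param_names]
    u = [sp.Symbol(c, real=True) for c in control_names]
    ns = {s.name: s for s in x + th + u}

    time_scale = sp.Rational(str(config.get("time_scale", 1)))
    rhs_exprs = []
    for s in state_names:
        expr = sp.sympify(config["rhs"][s], locals=ns)
        rhs_exprs.append(sp.expand(time_scale * expr))

    drift, fields = [], [[] for _ in u]
    for expr in rhs_exprs:
        sub0 = expr.subs({ui: 0 for ui in u})
        drift.append(sp.expand(sub0))
        rec = sub0
        for i, ui in enumerate(u):
            gi = sp.expand(sp.diff(expr, ui))
            for uj in u:
                if sp.diff(gi, uj) != 0:
                    raise ConfigurationError(
                        "model is not control-affine (nonlinear in stimuli)")
            fields[i].append(gi)
            rec = rec + ui * gi
        if sp.expand(rec - expr) != 0:
            raise ConfigurationError(
                "model is not control-affine (nonlinear in stimuli)")

    obs_defs = {}
    for oname, combo in config["observables"].items():
        obs_defs[oname] = {s: float(c) for s, c in combo.items()}
    obs_exprs = {o: sum(c * x[state_names.index(s)] for s, c in combo.items())
                 for o, combo in obs_defs.items()}

    init_cfg = config.get("initial", {"policy": "resting", "seed": {}})
    seed_exprs = [sp.sympify(str(init_cfg.get("seed", {}).get(s, 0)), locals=ns)
                  for s in state_names]

    sym = SymbolicModel(x, th, u, drift, fields, obs_exprs, seed_exprs)

    xv = sp.Matrix(x)
    thv = sp.Matrix(th)
    n = len(x)
    full = sp.Matrix(sym.rhs_exprs())
    Jx_expr = full.jacobian(xv)
    Jth_expr = full.jacobian(thv)
    args = (x, u if u else [sp.Symbol("_u")], th)
    f_rhs = _lambdify(args, full, shape=(n,))
    f_drift = _lambdify((x, th), sp.Matrix(drift), shape=(n,))
    f_fields = (_lambdify((x, th), sp.Matrix([g for gs in fields for g in gs]),
                          shape=(len(u), n)) if u
                else (lambda xx, tt: np.zeros((0, n))))
    f_jx = _lambdify(args, Jx_expr, shape=(n, n))
    f_jth = _lambdify(args, Jth_expr, shape=(n, len(th)))
    f_seed = _lambdify((th,), sp.Matrix(seed_exprs), shape=(n,))

    model = DynamicModel(
        name=name or config.get("name", "model"),
        state_names=state_names, param_names=param_names,
        control_names=control_names, observable_defs=obs_defs,
        rhs=f_rhs, drift=f_drift, control_fields=f_fields,
        jac_x=f_jx, jac_theta=f_jth, symbolic=sym,
        initial_condition_policy=init_cfg.get("policy", "resting"),
        seed_state=f_seed,
        fixed_initial=(f_seed(nominal)
                       if init_cfg.get("policy") == "fixed" else None),
    )
    space = ParameterSpace(param_names, nominal, free_mask, lower, upper)
    return model, space
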