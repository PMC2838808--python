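"""Global parameter ranking from Latin-hypercube samples of parameter space.

For every LHS draw the relative sensitivities of all observables at all
sampling times are computed, and per-parameter importance factors summarise
them over the whole scheme (Brun & Reichert style):

    delta_msqr = sqrt( (1/N_D) sum s_rel^2 )     delta_mabs = mean |s_rel|
    delta_mean = mean s_rel                      delta_max / delta_min

with N_D = n_lhs * n_e * n_o * n_s.  Ranking (by delta_msqr by default) over
several reference-centred ranges separates influential parameters from the
nearly inert ones, which are then fixed to their nominal values for
calibration (the theta_kappa partition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model_core import (ConfigurationError, DynamicModel, ExperimentDesign,
                         ParameterSpace, SimulationError)
from .sensitivity import (finite_difference_sensitivities,
                          forward_sensitivities, relative_sensitivities)

__all__ = ["LHSDesign", "ImportanceFactors", "lhs_sample",
           "importance_factors", "rank_parameters", "rank_over_ranges",
           "DEFAULT_RANGES"]

# Reference-centred sampling boxes (lower factor, upper factor) around the
# reference vector; log-uniform sampling within each.
DEFAULT_RANGES = [(0.5, 2.0), (0.1, 10.0), (1.0, 100.0)]

_FACTOR_COLS = ["msqr", "mabs", "mean", "max", "min"]


@dataclass
class LHSDesign:
    samples: np.ndarray          # (n_lhs, n_free), native units
    strata: np.ndarray           # (n_lhs, n_free) interval index per draw
    free_names: list[str]
    seed: int
    distribution: str

    @property
    def n(self) -> int:
        return self.samples.shape[0]


def lhs_sample(space: ParameterSpace, free_names: list[str], n_lhs: int,
               distribution: str = "log-uniform", seed: int = 0,
               lower: np.ndarray | None = None,
               upper: np.ndarray | None = None) -> LHSDesign:
    """Stratified sample: each parameter's range is split into n_lhs
    equal-probability intervals, one draw per interval, with the pairing
    across parameters randomly permuted (seeded)."""
    if n_lhs < 2:
        raise ConfigurationError("n_lhs must be at least 2")
    idx = space.indices(free_names)
    lo = np.asarray(lower if lower is not None else space.lower[idx], float)
    up = np.asarray(upper if upper is not None else space.upper[idx], float)
    if not (lo < up).all() or not np.isfinite(lo).all() \
            or not np.isfinite(up).all():
        raise ConfigurationError("finite lower < upper bounds required")
    sampler = qmc.LatinHypercube(d=len(free_names), seed=seed)
    unit = sampler.random(n_lhs)
    strata = np.floor(unit * n_lhs).astype(int)
    if distribution == "uniform":
        samples = lo + unit * (up - lo)
    elif distribution == "log-uniform":
        if (lo <= 0).any():
            raise ConfigurationError("log-uniform needs positive bounds")
        samples = np.exp(np.log(lo) + unit * (np.log(up) - np.log(lo)))
    else:
        raise ConfigurationError(f"unknown distribution {distribution!r}")
    return LHSDesign(samples, strata, list(free_names), seed, distribution)


@dataclass
class ImportanceFactors:
    table: pd.DataFrame          # index parameters, columns the five factors
    n_d: int                     # realised number of summands
    n_failed: int
    by_experiment: dict[str, pd.DataFrame] = field(default_factory=dict)
    by_observable: dict[str, pd.DataFrame] = field(default_factory=dict)


class _Accum:
    def __init__(self, f):
        self.sq = np.zeros(f)
        self.ab = np.zeros(f)
        self.sm = np.zeros(f)
        self.mx = np.full(f, -np.inf)
        self.mn = np.full(f, np.inf)
        self.n = 0

    def add(self, s):                      # s: (n_s, f)
        self.sq += (s ** 2).sum(axis=0)
        self.ab += np.abs(s).sum(axis=0)
        self.sm += s.sum(axis=0)
        self.mx = np.maximum(self.mx, s.max(axis=0))
        self.mn = np.minimum(self.mn, s.min(axis=0))
        self.n += s.shape[0]

    def table(self, names):
        n = max(self.n, 1)
        return pd.DataFrame(
            {"msqr": np.sqrt(self.sq / n), "mabs": self.ab / n,
             "mean": self.sm / n,
             "max": np.where(np.isfinite(self.mx), self.mx, 0.0),
             "min": np.where(np.isfinite(self.mn), self.mn, 0.0)},
            index=names)


def importance_factors(model: DynamicModel, space: ParameterSpace,
                       designs: list[ExperimentDesign], lhs: LHSDesign,
                       floor: float = 1e-8, engine: str = "magnus",
                       dense_dt: float = 0.25, rtol: float = 1e-7,
                       atol: float = 1e-10, max_failed_frac: float = 0.2
                       ) -> ImportanceFactors:
    """The five importance factors per parameter over all LHS draws,
    experiments, observables and sampling times, plus per-experiment and
    per-observable slices.  Draws whose simulation fails are excluded and
    counted; more than `max_failed_frac` failures aborts (the sampling
    range is then considered pathological)."""
    names = lhs.free_names
    f = len(names)
    idx = space.indices(names)
    total = _Accum(f)
    per_e = {d.name: _Accum(f) for d in designs}
    per_o = {}
    failed = 0
    for row in lhs.samples:
        theta = space.nominal.copy()
        theta[idx] = row
        try:
            draws = []
            for d in designs:
                if engine == "fd":
                    sens = finite_difference_sensitivities(
                        model, theta, d, names, rtol=rtol, atol=atol)
                else:
                    sens = forward_sensitivities(
                        model, theta, d, names, rtol=rtol, atol=atol,
                        engine=engine, dense_dt=dense_dt)
                draws.append(relative_sensitivities(sens, theta, model,
                                                    floor=floor))
        except SimulationError:
            failed += 1
            continue
        for d, rel in zip(designs, draws):
            for o in d.observables:
                s = rel.s_rel[o]
                total.add(s)
                per_e[d.name].add(s)
                per_o.setdefault(o, _Accum(f)).add(s)
    if failed > max_failed_frac * lhs.n:
        raise SimulationError(
            f"{failed}/{lhs.n} LHS draws failed; sampling range pathological")
    return ImportanceFactors(
        table=total.table(names), n_d=total.n, n_failed=failed,
        by_experiment={k: v.table(names) for k, v in per_e.items()},
        by_observable={k: v.table(names) for k, v in per_o.items()})


def factors_to_csv(factors: ImportanceFactors, prefix) -> list[str]:
    """Write the global factor table plus the per-experiment and
    per-observable slice tables (one file each)."""
    paths = []

    def put(tag, df):
        path = f"{prefix}_{tag}.csv"
        df.to_csv(path)
        paths.append(path)

    put("global", factors.table)
    for name, df in factors.by_experiment.items():
        put(f"experiment_{name}", df)
    for name, df in factors.by_observable.items():
        put(f"observable_{name}", df)
    return paths


def rank_parameters(factors: ImportanceFactors | pd.DataFrame,
                    criterion: str = "msqr",
                    partition_fraction: float = 0.01
                    ) -> tuple[pd.DataFrame, dict]:
    """Ranking in decreasing order of the chosen factor (ties broken
    lexicographically by name, so the order is deterministic) and a
    partition suggestion: parameters whose factor falls below
    `partition_fraction` of the top value are proposed for fixing."""
    table = factors.table if isinstance(factors, ImportanceFactors) else factors
    if criterion not in table.columns:
        raise ConfigurationError(f"unknown criterion {criterion!r}")
    key = table[criterion].abs()
    order = sorted(table.index, key=lambda n: (-key[n], n))
    ranked = table.loc[order].copy()
    ranked.insert(0, "rank", np.arange(1, len(order) + 1))
    top = key[order[0]]
    fix = [n for n in order if key[n] < partition_fraction * top]
    keep = [n for n in table.index if n not in set(fix)]
    return ranked, {"estimate": keep, "fix": fix,
                    "criterion": criterion,
                    "threshold": float(partition_fraction * top)}


def rank_over_ranges(model: DynamicModel, space: ParameterSpace,
                     designs: list[ExperimentDesign], free_names: list[str],
                     n_lhs: int, ranges=None, seed: int = 0,
                     criterion: str = "msqr", **kw
                     ) -> tuple[pd.DataFrame, dict, dict]:
    """Importance factors over several reference-centred ranges and the
    ranking by the factors' mean across ranges (the range-robust ranking
    used to decide the theta_kappa partition)."""
    ranges = ranges or DEFAULT_RANGES
    idx = space.indices(free_names)
    ref = space.nominal[idx]
    per_range = {}
    acc = None
    for k, (lo_f, up_f) in enumerate(ranges):
        lhs = lhs_sample(space, free_names, n_lhs, seed=seed + k,
                         lower=ref * lo_f, upper=ref * up_f)
        fac = importance_factors(model, space, designs, lhs, **kw)
        per_range[f"range_{lo_f}_{up_f}"] = fac
        acc = fac.table[[criterion]].copy() if acc is None \
            else acc + fac.table[[criterion]]
    mean_table = acc / len(ranges)
    ranked, partition = rank_parameters(
        mean_table.rename(columns={criterion: criterion}), criterion)
    return ranked, partition, per_range
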