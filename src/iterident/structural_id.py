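"""Structural identifiability from power-series expansions of the observables.

The observables of a control-affine model are expanded around t = 0+ either
as a Maclaurin series in time under a fixed stimulus (Taylor variant) or as
a generating series with respect to time and the stimuli, whose coefficients
are the observation functions and their iterated Lie derivatives

    L_F h = sum_j  dh/dx_j  F_j

along the drift field f and the stimulus-coupled fields g_i, evaluated at
the known initial state.  With x(0) substituted, each coefficient is a pure
function of the parameters; the parameters are (locally) identifiable when
the Jacobian of the coefficient vector with respect to the free parameters
reaches full column rank.  The identifiability tableau is the boolean
pattern of that Jacobian; its minimum variant (first rows, in series order,
achieving full rank) supports an elimination procedure: a row with a single
surviving mark pins down a parameter, which removes its column, and small
remaining subsystems are solved symbolically to count solution multiplicity.

Coefficient expressions are kept fully symbolic; rank and tableau-sparsity
questions are settled numerically (complex-step Jacobians at several random
parameter draws), which for large models yields *local* structural
identifiability — the verdict records this.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .model_core import ConfigurationError, DynamicModel, ParameterSpace

__all__ = ["CoefficientEntry", "SeriesCoefficientSet", "RankReport",
           "IdentifiabilityTableau", "ReductionTrace", "series_coefficients",
           "coefficient_jacobian_rank", "build_tableau", "reduce_tableau",
           "analyze_structural_identifiability", "tableau_to_csv",
           "reduction_report"]

_ZERO_TOL = 1e-12       # structural-zero threshold, relative to row scale
_RANK_TOL = 1e-8        # singular values below tol*s_max count as zero


@dataclass
class CoefficientEntry:
    observable: str
    word: tuple[str, ...]       # Lie-derivative word, applied left to right
    order: int
    expr: sp.Expr               # symbolic in states and all parameters

    @property
    def label(self) -> str:
        if not self.word:
            return self.observable
        return "L_" + " L_".join(self.word) + f" {self.observable}"


@dataclass
class SeriesCoefficientSet:
    method: str                             # "taylor" | "generating"
    entries: list[CoefficientEntry]
    free_names: list[str]
    x0: np.ndarray
    nominal_free: np.ndarray
    fixed_values: dict[str, float] = None   # fixed parameters baked in
    zero_flags: np.ndarray = None           # germ-zero coefficients at x0
    _eval: callable = None                  # theta_free -> coefficient vector

    @property
    def nonzero_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.zero_flags)

    def evaluate(self, theta_free: np.ndarray) -> np.ndarray:
        return self._eval(theta_free)

    def jacobian(self, theta_free: np.ndarray) -> np.ndarray:
        """Complex-step Jacobian d s_i / d theta_j (machine precision for
        the polynomial coefficient functions)."""
        th = np.asarray(theta_free, complex)
        J = np.empty((len(self.entries), th.size))
        for j in range(th.size):
            h = 1e-100 * max(abs(th[j].real), 1.0)
            tp = th.copy()
            tp[j] += 1j * h
            J[:, j] = np.imag(self.evaluate(tp)) / h
        return J


def _lie(h: sp.Expr, F: list[sp.Expr], xs: list[sp.Symbol]) -> sp.Expr:
    # no expansion: factored derivative trees stay exponentially smaller
    # over iterated application, and evaluation goes through CSE anyway
    return sp.Add(*[sp.diff(h, xj) * Fj for xj, Fj in zip(xs, F)
                    if Fj != 0 and sp.diff(h, xj) != 0])


def series_coefficients(model: DynamicModel, x0: np.ndarray,
                        free_names: list[str], method: str = "generating",
                        max_order: int = 3, u_value: float = 1.0,
                        nominal: np.ndarray | None = None,
                        n_zero_test: int = 5, seed: int = 0,
                        observables: list[str] | None = None
                        ) -> SeriesCoefficientSet:
    """All derivative words up to `max_order` for every observable.

    method="generating" uses the alphabet {f, g1, ...} of drift and stimulus
    fields (requires the control-affine decomposition); method="taylor" uses
    the single field f + sum u_i g_i at the constant stimulus `u_value`.
    Coefficients that vanish identically in the parameters (given x0) are
    flagged, not dropped — an all-zero germ carries no information.
    """
    sym = model.symbolic
    if sym is None:
        raise ConfigurationError("model has no symbolic definition")
    xs = sym.x
    if method == "generating":
        fields = [("f", sym.drift)] + [
            (f"g{i+1}", g) for i, g in enumerate(sym.fields)]
    elif method == "taylor":
        total = [sp.expand(d + sum(float(u_value) * g[k]
                                   for g in sym.fields))
                 for k, d in enumerate(sym.drift)]
        fields = [("f", total)]
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    obs_names = observables or list(sym.observables)
    # series order: all order-0 coefficients first, then order 1, ... so the
    # "first rows" of the tableau really are the lowest-order coefficients
    per_obs = {o: {(): sym.observables[o]} for o in obs_names}
    entries: list[CoefficientEntry] = [
        CoefficientEntry(o, (), 0, per_obs[o][()]) for o in obs_names]
    for order in range(1, max_order + 1):
        for oname in obs_names:
            nxt = {}
            for word, expr in per_obs[oname].items():
                for fname, F in fields:
                    w = word + (fname,)
                    e = _lie(expr, F, xs)
                    nxt[w] = e
                    entries.append(CoefficientEntry(oname, w, order, e))
            per_obs[oname] = nxt

    free_syms = [sp.Symbol(n, real=True) for n in free_names]
    name_to_sym = {s.name: s for s in sym.theta}
    fixed_syms = [s for s in sym.theta if s.name not in set(free_names)]
    nominal = np.asarray(nominal, float) if nominal is not None else None
    if nominal is None:
        raise ConfigurationError("nominal parameter vector required")
    pidx = {n: i for i, n in enumerate(model.param_names)}
    fixed_vals = np.array([nominal[pidx[s.name]] for s in fixed_syms])
    nominal_free = np.array([nominal[pidx[n]] for n in free_names])

    exprs = [e.expr for e in entries]
    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 100000))
    try:
        fn = sp.lambdify((xs, [name_to_sym[n] for n in free_names],
                          fixed_syms), exprs, modules="numpy", cse=True)
    finally:
        sys.setrecursionlimit(old_limit)
    x0 = np.asarray(x0, float)

    def evaluate(theta_free):
        return np.asarray(fn(x0, np.asarray(theta_free), fixed_vals))

    out = SeriesCoefficientSet(method, entries, list(free_names), x0,
                               nominal_free,
                               fixed_values={s.name: float(v) for s, v in
                                             zip(fixed_syms, fixed_vals)})
    out._eval = evaluate

    rng = np.random.default_rng(seed)
    draws = [nominal_free * rng.uniform(0.5, 2.0, nominal_free.size)
             for _ in range(n_zero_test)]
    vals = np.array([np.abs(out.evaluate(d)) for d in draws])  # (draws, n)
    per_obs_scale = {}
    for oname in obs_names:
        idx = [i for i, e in enumerate(entries) if e.observable == oname]
        per_obs_scale[oname] = max(vals[:, idx].max(), 1e-300)
    zero = np.empty(len(entries), bool)
    for i, e in enumerate(entries):
        zero[i] = vals[:, i].max() < _ZERO_TOL * per_obs_scale[e.observable]
    out.zero_flags = zero
    return out


@dataclass
class RankReport:
    rank: int
    n_free: int
    per_point_ranks: list[int]
    empty_columns: list[str]
    deficiency_groups: list[list[str]]
    full_rank: bool


def _scaled_jacobian(coeffs: SeriesCoefficientSet, theta_free: np.ndarray,
                     rows: np.ndarray | None = None) -> np.ndarray:
    """Jacobian in relative coordinates: columns scaled by theta_j, rows
    normalised — makes the rank test meaningful across wildly different
    coefficient units."""
    J = coeffs.jacobian(theta_free)
    J = J * np.asarray(theta_free)[None, :]
    if rows is not None:
        J = J[rows]
    norms = np.abs(J).max(axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return J / norms


def coefficient_jacobian_rank(coeffs: SeriesCoefficientSet,
                              n_test_points: int = 3, seed: int = 0,
                              rank_tol: float = _RANK_TOL) -> RankReport:
    """Numeric rank of d s / d theta over the non-zero coefficients, taken
    as the maximum over several random parameter draws; deficiency report
    names empty columns and null-space parameter groups."""
    rng = np.random.default_rng(seed)
    rows = coeffs.nonzero_indices
    if rows.size == 0:
        raise ConfigurationError("germ is not informative (all coefficients zero)")
    f = len(coeffs.free_names)
    ranks, best = [], None
    for _ in range(n_test_points):
        th = coeffs.nominal_free * rng.uniform(0.5, 2.0, f)
        J = _scaled_jacobian(coeffs, th, rows)
        if not np.isfinite(J).all():
            continue
        s = np.linalg.svd(J, compute_uv=False)
        r = int((s > rank_tol * max(s[0], 1e-300)).sum())
        ranks.append(r)
        if best is None or r >= max(ranks):
            best = (J, th)
    if not ranks:
        raise ConfigurationError("coefficient evaluation failed at all test points")
    rank = max(ranks)
    J, th = best
    colnorm = np.abs(J).max(axis=0)
    empty = [coeffs.free_names[j] for j in np.flatnonzero(colnorm
                                                          < _ZERO_TOL)]
    groups = []
    if rank < f:
        _, s, Vt = np.linalg.svd(J)
        null = Vt[rank:]
        for v in null:
            members = [coeffs.free_names[j]
                       for j in np.flatnonzero(np.abs(v) > 0.1 * np.abs(v).max())]
            if members and members not in groups:
                groups.append(members)
    return RankReport(rank, f, ranks, empty, groups, rank == f)


@dataclass
class IdentifiabilityTableau:
    matrix: np.ndarray                   # boolean, rows x free parameters
    row_entries: list[int]               # indices into coeffs.entries
    col_names: list[str]
    variant: str                         # full | minimum | reduced-k

    def row_labels(self, coeffs: SeriesCoefficientSet) -> list[str]:
        return [coeffs.entries[i].label for i in self.row_entries]


def build_tableau(coeffs: SeriesCoefficientSet, n_test_points: int = 5,
                  seed: int = 0, rank_tol: float = _RANK_TOL,
                  partial: bool = False
                  ) -> tuple[IdentifiabilityTableau,
                             IdentifiabilityTableau | None]:
    """Full tableau (boolean dependency pattern of the non-zero coefficients
    on the free parameters, detected at several random draws) and the
    minimum variant: the first rows, in series order, whose Jacobian already
    has full column rank.  The minimum variant is refused (None) when the
    full Jacobian is rank deficient."""
    rng = np.random.default_rng(seed)
    rows = coeffs.nonzero_indices
    f = len(coeffs.free_names)
    dep = np.zeros((rows.size, f), bool)
    Js, ranks = [], []
    for _ in range(n_test_points):
        th = coeffs.nominal_free * rng.uniform(0.5, 2.0, f)
        J = _scaled_jacobian(coeffs, th, rows)
        Js.append(J)
        s = np.linalg.svd(J, compute_uv=False)
        ranks.append(int((s > rank_tol * max(s[0], 1e-300)).sum()))
        dep |= np.abs(J) > _ZERO_TOL
    full = IdentifiabilityTableau(dep, list(rows), list(coeffs.free_names),
                                  "full")
    target = max(ranks)
    J = Js[int(np.argmax(ranks))]
    selected: list[int] = []
    acc = np.zeros((0, f))
    rank = 0
    for i in range(rows.size):
        trial = np.vstack([acc, J[i][None, :]])
        s = np.linalg.svd(trial, compute_uv=False)
        r = int((s > rank_tol * max(s[0], 1e-300)).sum())
        if r > rank:
            selected.append(i)
            acc = trial
            rank = r
            if rank == target:
                break
    if rank < f and not partial:
        return full, None
    minimum = IdentifiabilityTableau(dep[selected],
                                     [rows[i] for i in selected],
                                     list(coeffs.free_names),
                                     "minimum" if rank == f else "partial")
    return full, minimum


@dataclass
class ReductionTrace:
    steps: list[dict]
    verdicts: dict[str, str]     # unique | finite-multiple | unresolved
    overall: str                 # structurally identifiable | locally
    #                              identifiable | unidentifiable | inconclusive


def reduce_tableau(minimum: IdentifiabilityTableau,
                   coeffs: SeriesCoefficientSet, model: DynamicModel,
                   max_subset_size: int = 3, max_expr_len: int = 20000,
                   enable_solve: bool = True) -> ReductionTrace:
    """Iterated elimination on the minimum tableau.  Rows with a single
    surviving mark solve their parameter (solution multiplicity from the
    polynomial degree or a symbolic solve) and delete its column; when no
    single-mark rows remain, small connected subsystems are solved
    symbolically to count solutions.  Anything that resists is reported
    unresolved — never guessed."""
    if minimum is None or minimum.variant not in ("minimum", "partial"):
        raise ConfigurationError("reduction needs a minimum tableau")
    if minimum.variant == "partial":
        # under a rank-deficient Jacobian only the single-mark elimination
        # chain is sound; under-determined subsystems are left unresolved
        enable_subsystems = False
    else:
        enable_subsystems = True
    sym = model.symbolic
    xsub = {s: sp.Float(v) for s, v in zip(sym.x, coeffs.x0)}
    fix_vals = {s: sp.Float(coeffs.fixed_values[s.name]) for s in sym.theta
                if s.name in coeffs.fixed_values}
    free_syms = {s.name: s for s in sym.theta
                 if s.name not in coeffs.fixed_values}

    def reduced_expr(entry_idx: int) -> sp.Expr:
        e = coeffs.entries[entry_idx]
        return sp.expand(e.expr.xreplace(xsub).xreplace(fix_vals))

    M = minimum.matrix.copy()
    names = list(minimum.col_names)
    active = {n: True for n in names}
    verdicts: dict[str, str] = {}
    steps: list[dict] = []

    def multiplicity_single(expr: sp.Expr, pname: str) -> str:
        p = free_syms[pname]
        try:
            poly = sp.Poly(expr, p)
            deg = poly.degree()
            return "unique" if deg <= 1 else "finite-multiple"
        except sp.PolynomialError:
            try:
                sols = sp.solve(sp.Eq(expr, sp.Symbol("_s")), p)
                return "unique" if len(sols) == 1 else "finite-multiple"
            except Exception:
                return "unique"  # single-mark row: identifiable by the
                # tableau rule; multiplicity could not be counted

    changed = True
    step_no = 0
    while changed:
        changed = False
        for i in range(M.shape[0]):
            cols = [j for j in range(M.shape[1])
                    if M[i, j] and active[names[j]]]
            if len(cols) == 1:
                j = cols[0]
                pname = names[j]
                step_no += 1
                mult = "unique"
                if enable_solve:
                    expr = reduced_expr(minimum.row_entries[i])
                    if len(sp.srepr(expr)) <= max_expr_len:
                        mult = multiplicity_single(expr, pname)
                verdicts[pname] = mult
                steps.append({"step": step_no, "parameters": [pname],
                              "rows": [int(minimum.row_entries[i])],
                              "multiplicity": mult, "kind": "single-mark"})
                active[pname] = False
                changed = True

    remaining = [n for n in names if active[n]]
    if remaining and enable_solve and enable_subsystems:
        # connected components of the remaining row/parameter graph
        comp_of = {n: {n} for n in remaining}
        for i in range(M.shape[0]):
            cols = [names[j] for j in range(M.shape[1])
                    if M[i, j] and active[names[j]]]
            if len(cols) > 1:
                merged = set().union(*(comp_of[c] for c in cols))
                for c in merged:
                    comp_of[c] = merged
        seen = []
        for comp in comp_of.values():
            if comp in seen:
                continue
            seen.append(comp)
            params = sorted(comp)
            if len(params) > max_subset_size:
                for p in params:
                    verdicts[p] = "unresolved"
                continue
            rows_i = [i for i in range(M.shape[0])
                      if any(M[i, names.index(p)] for p in params)
                      and all(not M[i, j] or not active[names[j]]
                              or names[j] in comp
                              for j in range(M.shape[1]))]
            exprs, labels = [], []
            for i in rows_i[: len(params) + 2]:
                e = reduced_expr(minimum.row_entries[i])
                if len(sp.srepr(e)) > max_expr_len:
                    continue
                exprs.append(sp.Eq(e, sp.Symbol(f"_s{i}")))
                labels.append(int(minimum.row_entries[i]))
            mult = "unresolved"
            if len(exprs) >= len(params):
                try:
                    sols = sp.solve(exprs, [free_syms[p] for p in params],
                                    dict=True)
                    if len(sols) == 1:
                        mult = "unique"
                    elif len(sols) > 1:
                        mult = "finite-multiple"
                except Exception:
                    mult = "unresolved"
            step_no += 1
            steps.append({"step": step_no, "parameters": params,
                          "rows": labels, "multiplicity": mult,
                          "kind": "subsystem"})
            for p in params:
                verdicts[p] = mult
                active[p] = False
    for n in names:
        verdicts.setdefault(n, "unresolved")

    vals = set(verdicts.values())
    if vals == {"unique"}:
        overall = "structurally identifiable"
    elif "unresolved" in vals:
        overall = "inconclusive"
    else:
        overall = "locally identifiable"
    return ReductionTrace(steps, verdicts, overall)


def analyze_structural_identifiability(
        model: DynamicModel, space: ParameterSpace, x0: np.ndarray,
        free_names: list[str] | None = None, method: str = "generating",
        max_order: int = 8, start_order: int = 1, seed: int = 0,
        observables: list[str] | None = None) -> dict:
    """Grow the series until the numeric Jacobian rank is stable for two
    consecutive orders (or the order cap is hit), then build the tableaus
    and run the reduction.  Returns a dict with the coefficient set, rank
    report, tableaus and reduction trace."""
    free_names = free_names or space.free_names
    prev_rank, coeffs, rank = -1, None, None
    for order in range(start_order, max_order + 1):
        coeffs = series_coefficients(model, x0, free_names, method=method,
                                     max_order=order, nominal=space.nominal,
                                     seed=seed, observables=observables)
        if coeffs.nonzero_indices.size == 0:
            continue  # germ not informative yet: grow the series
        rank = coefficient_jacobian_rank(coeffs, seed=seed)
        if rank.full_rank or rank.rank == prev_rank:
            break
        prev_rank = rank.rank
    if rank is None:
        raise ConfigurationError(
            "germ is not informative up to the order cap")
    full, minimum = build_tableau(coeffs, seed=seed, partial=True)
    trace = None
    if minimum is not None:
        trace = reduce_tableau(minimum, coeffs, model)
    if not rank.full_rank:
        verdict = "unidentifiable"
    elif trace is not None and trace.overall in (
            "structurally identifiable", "locally identifiable"):
        verdict = trace.overall
    else:
        # numeric full-rank certificate without a complete symbolic
        # reduction can only establish local identifiability
        verdict = "locally identifiable"
    return {"coefficients": coeffs, "rank": rank, "tableau_full": full,
            "tableau_minimum": minimum, "reduction": trace,
            "order_used": coeffs.entries[-1].order, "verdict": verdict}


def tableau_to_csv(tableau: IdentifiabilityTableau,
                   coeffs: SeriesCoefficientSet, path) -> None:
    import pandas as pd
    df = pd.DataFrame(tableau.matrix.astype(int),
                      index=tableau.row_labels(coeffs),
                      columns=tableau.col_names)
    df.to_csv(path)


def reduction_report(trace: ReductionTrace) -> str:
    lines = [f"overall verdict: {trace.overall}", ""]
    for st in trace.steps:
        lines.append(f"step {st['step']:2d} [{st['kind']}] "
                     f"solve {', '.join(st['parameters'])} "
                     f"from rows {st['rows']} -> {st['multiplicity']}")
    lines.append("")
    for p, v in trace.verdicts.items():
        lines.append(f"{p}: {v}")
    return "\n".join(lines)
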