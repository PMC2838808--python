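"""Monte-Carlo practical identifiability analysis.

Hundreds of in-silico replicates of an experimental scheme are generated
(truth + heteroscedastic Gaussian noise), the model is re-calibrated against
each, and the resulting cloud of estimates is summarised: per-coordinate
trimming to the [0.05, 0.95] quantile box, normalisation by the trimmed
mean, principal-axis decomposition of the normalised cloud, pairwise
ellipse eccentricities (parameter correlation), pseudo-volume (overall
accuracy), expected uncertainties C_theta / C% and — when the generating
truth is known (a-priori mode) — the relative bias delta%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationProblem, OptimizerConfig, calibrate
from .model_core import (ConfigurationError, DynamicModel, ExperimentDesign,
                         MeasurementSet, NoiseSpec, ParameterSpace,
                         SimulationError, generate_noisy_replicate,
                         predict_observables)

__all__ = ["SolutionCloud", "EllipsoidFit", "UncertaintyReport",
           "monte_carlo_cloud", "trim_and_fit", "uncertainty_report",
           "cost_contours", "ECCENTRICITY_CAP"]

ECCENTRICITY_CAP = 1e3


@dataclass
class SolutionCloud:
    estimates: np.ndarray            # (n_ok, n_free)
    costs: np.ndarray
    free_names: list[str]
    master_seed: int
    n_requested: int
    theta_ref: np.ndarray | None = None   # generating truth (a-priori mode)
    mode: str = "a_priori"

    @property
    def n_replicates(self) -> int:
        return self.estimates.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.estimates, columns=self.free_names)
        df.insert(0, "J", self.costs)
        return df


@dataclass
class EllipsoidFit:
    directions: np.ndarray           # rows: principal axes (orthonormal)
    lengths: np.ndarray              # semi-axis lengths, descending
    mean: np.ndarray                 # trimmed mean used for normalisation
    pairwise_ecc: np.ndarray         # (f, f), 1 on the diagonal
    degenerate_pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class UncertaintyReport:
    table: pd.DataFrame              # per parameter: mu, delta_pct, C_theta, C_pct
    eccentricity: pd.DataFrame       # pairwise axis ratios
    max_ecc_pair: tuple[str, str]
    max_ecc: float
    pseudo_volume: float


def _replicate_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n)


def monte_carlo_cloud(model: DynamicModel, space: ParameterSpace,
                      scheme: list[ExperimentDesign], free_names: list[str],
                      theta_true: np.ndarray | None = None,
                      data: list[MeasurementSet] | None = None,
                      n_reps: int = 200,
                      noise_spec: NoiseSpec | None = None,
                      optimizer: OptimizerConfig | None = None,
                      master_seed: int = 0, rtol: float = 1e-7,
                      atol: float = 1e-10,
                      base_theta: np.ndarray | None = None) -> SolutionCloud:
    """Replicate calibrations under fresh noise.

    A-priori mode (theta_true given): noiseless predictions at the truth are
    perturbed with `noise_spec` per replicate.  A-posteriori mode (data
    given): the model is first fitted to the data, the noise level is
    estimated from the weighted residuals, and replicates are resampled
    around the fitted predictions.  Replicate r's noise stream depends only
    on (master_seed, r), so the cloud is independent of execution order.
    """
    noise_spec = noise_spec or NoiseSpec()
    free_idx = space.indices(free_names)

    if theta_true is not None:
        mode = "a_priori"
        theta_gen = np.asarray(theta_true, float)
        start = theta_gen[free_idx]
    elif data is not None:
        mode = "a_posteriori"
        prob0 = CalibrationProblem(model, space, data, list(free_names),
                                   rtol=rtol, atol=atol, base_theta=base_theta)
        fit0 = calibrate(prob0, optimizer, seed=master_seed)
        theta_gen = prob0.full_theta(fit0.theta_hat)
        # residual-based noise estimate: scale the assumed relative level by
        # the observed weighted-residual RMS
        r = prob0.residuals(fit0.theta_hat)
        scale = float(np.sqrt(np.mean(r ** 2)))
        noise_spec = NoiseSpec(rel=noise_spec.rel * max(scale, 1e-6),
                               floor=noise_spec.floor)
        start = fit0.theta_hat
    else:
        raise ConfigurationError("need theta_true (a priori) or data")

    x0 = model.x0_for(theta_gen, rtol=rtol, atol=atol)
    noiseless = [predict_observables(model, theta_gen, d, x0=x0,
                                     rtol=rtol, atol=atol) for d in scheme]

    opt = optimizer or OptimizerConfig.warm(start)
    seeds = _replicate_seeds(master_seed, n_reps)
    rows, costs, failures = [], [], 0
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        try:
            datasets = [generate_noisy_replicate(nl, noise_spec, rng)
                        for nl in noiseless]
            prob = CalibrationProblem(model, space, datasets,
                                      list(free_names), rtol=rtol, atol=atol,
                                      base_theta=base_theta)
            res = calibrate(prob, opt, seed=int(ss.generate_state(1)[0]
                                                % (2 ** 31)))
            rows.append(res.theta_hat)
            costs.append(res.cost)
        except SimulationError:
            failures += 1
    if len(rows) < 0.5 * n_reps:
        raise SimulationError(
            f"only {len(rows)}/{n_reps} replicate fits succeeded")
    return SolutionCloud(np.array(rows), np.array(costs), list(free_names),
                         master_seed, n_reps,
                         theta_ref=(theta_gen[free_idx]
                                    if mode == "a_priori" else None),
                         mode=mode)


def trim_and_fit(cloud: SolutionCloud) -> tuple[EllipsoidFit, np.ndarray]:
    """Trim the cloud to its per-coordinate [0.05, 0.95] quantile box (robust
    against estimates piling at the bounds), normalise coordinates by their
    trimmed means, and decompose the covariance into principal axes."""
    X = cloud.estimates
    if X.shape[0] < 20:
        raise ConfigurationError("need at least 20 replicates to fit")
    q05 = np.quantile(X, 0.05, axis=0)
    q95 = np.quantile(X, 0.95, axis=0)
    inside = ((X >= q05) & (X <= q95)).all(axis=1)
    T = X[inside]
    mean = T.mean(axis=0)
    denom = np.where(np.abs(mean) > 0, mean, 1.0)
    Z = T / denom
    C = np.cov(Z.T) if T.shape[0] > 1 else np.zeros((X.shape[1], X.shape[1]))
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    lengths = np.sqrt(np.clip(evals[order], 0, None))
    directions = evecs[:, order].T

    f = X.shape[1]
    ecc = np.ones((f, f))
    degenerate = []
    # pairwise eccentricity measures correlation, so each coordinate is
    # standardised to unit variance first: the 2-D ellipse axis ratio is
    # then sqrt((1+|rho|)/(1-|rho|)).  Without this, pairs of parameters
    # with very different relative uncertainties would show large axis
    # ratios even when completely uncorrelated.
    d = np.sqrt(np.clip(np.diag(C), 0, None))
    for i in range(f):
        for j in range(i + 1, f):
            if d[i] == 0 or d[j] == 0:
                val = ECCENTRICITY_CAP
                degenerate.append((i, j))
            else:
                rho = abs(C[i, j] / (d[i] * d[j]))
                rho = min(rho, 1.0)
                if 1.0 - rho <= 2.0 / (1.0 + ECCENTRICITY_CAP ** 2):
                    val = ECCENTRICITY_CAP
                    degenerate.append((i, j))
                else:
                    val = float(np.sqrt((1 + rho) / (1 - rho)))
            ecc[i, j] = ecc[j, i] = val
    return EllipsoidFit(directions, lengths, mean, ecc, degenerate), T


def uncertainty_report(cloud: SolutionCloud, fit: EllipsoidFit,
                       theta_star: np.ndarray | None = None,
                       c_mode: str = "halfwidth") -> UncertaintyReport:
    """Per-parameter summary: mu (trimmed mean), delta% (relative distance of
    mu to the nominal, a-priori mode only), C_theta (half-width of the
    [0.05, 0.95] interval of the cloud, or max deviation from mu when
    c_mode="maxdev") and C% = 100 C_theta / mu; plus the pairwise
    eccentricities and the pseudo-volume (product of all semi-axes of the
    normalised ellipsoid)."""
    X = cloud.estimates
    names = cloud.free_names
    mu = fit.mean
    q05 = np.quantile(X, 0.05, axis=0)
    q95 = np.quantile(X, 0.95, axis=0)
    if c_mode == "halfwidth":
        C_theta = 0.5 * (q95 - q05)
    elif c_mode == "maxdev":
        C_theta = np.abs(X - mu).max(axis=0)
    else:
        raise ConfigurationError(f"unknown c_mode {c_mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        C_pct = 100.0 * C_theta / np.abs(mu)
    ref = theta_star if theta_star is not None else cloud.theta_ref
    if ref is not None:
        delta_pct = 100.0 * np.abs(mu - ref) / np.abs(ref)
    else:
        delta_pct = np.full(len(names), np.nan)
    table = pd.DataFrame({"mu": mu, "delta_pct": delta_pct,
                          "C_theta": C_theta, "C_pct": C_pct}, index=names)
    ecc = pd.DataFrame(fit.pairwise_ecc, index=names, columns=names)
    masked = fit.pairwise_ecc - np.eye(len(names))
    i, j = np.unravel_index(np.argmax(masked), masked.shape)
    return UncertaintyReport(table=table, eccentricity=ecc,
                             max_ecc_pair=(names[min(i, j)], names[max(i, j)]),
                             max_ecc=float(fit.pairwise_ecc[i, j]),
                             pseudo_volume=float(np.prod(fit.lengths)))


def cloud_to_csv(cloud: SolutionCloud, path) -> None:
    """One row per replicate: cost J followed by the estimates."""
    cloud.to_frame().to_csv(path, index=False, float_format="%.17g")


def contours_to_csv(contour: dict, path) -> None:
    """Long-format grid: value of each pair coordinate and J."""
    gi, gj, J = contour["grid_i"], contour["grid_j"], contour["J"]
    rows = [(gi[a], gj[b], J[a, b])
            for a in range(gi.size) for b in range(gj.size)]
    pd.DataFrame(rows, columns=[contour["pair"][0], contour["pair"][1],
                                "J"]).to_csv(path, index=False)


def cost_contours(problem: CalibrationProblem, pair: tuple[str, str],
                  n_grid: int = 25, span: float = 4.0,
                  center: np.ndarray | None = None,
                  level_delta: float = 5.99) -> dict:
    """J on a 2-D log-spaced grid over `pair`, the other free parameters held
    at `center`.  The sub-level set {J <= Jmin + level_delta} (default: the
    chi-square 95% offset for two parameters) flags a correlation valley
    (anisotropic set) and non-identifiability (set touching the grid
    boundary)."""
    i = problem.free_names.index(pair[0])
    j = problem.free_names.index(pair[1])
    c = np.asarray(center if center is not None else
                   problem.space.nominal[problem.free_idx], float)
    gi = np.geomspace(max(c[i] / span, problem.lower[i]),
                      min(c[i] * span, problem.upper[i]), n_grid)
    gj = np.geomspace(max(c[j] / span, problem.lower[j]),
                      min(c[j] * span, problem.upper[j]), n_grid)
    J = np.empty((n_grid, n_grid))
    for a, vi in enumerate(gi):
        for b, vj in enumerate(gj):
            th = c.copy()
            th[i], th[j] = vi, vj
            J[a, b] = problem.cost(th)
    if not np.isfinite(J).any() or J.min() >= 1e9:
        raise SimulationError("cost failed on the whole contour grid")
    sub = J <= J.min() + level_delta
    rows = np.flatnonzero(sub.any(axis=1))
    cols = np.flatnonzero(sub.any(axis=0))
    open_ended = bool(rows[0] == 0 or rows[-1] == n_grid - 1
                      or cols[0] == 0 or cols[-1] == n_grid - 1)
    # valley shape: principal-axis ratio of the sub-level set in log coords
    ii, jj = np.nonzero(sub)
    pts = np.c_[np.log(gi[ii]), np.log(gj[jj])]
    if pts.shape[0] > 2:
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        anisotropy = float(s[0] / max(s[1], s[0] / ECCENTRICITY_CAP))
    else:
        anisotropy = 1.0
    return {"grid_i": gi, "grid_j": gj, "J": J, "pair": pair,
            "min": float(J.min()),
            "argmin": (float(gi[np.unravel_index(J.argmin(), J.shape)[0]]),
                       float(gj[np.unravel_index(J.argmin(), J.shape)[1]])),
            "valley_anisotropy": float(anisotropy),
            "open_ended": open_ended}
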