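"""Monte-Carlo clouds, trimmed-ellipsoid analysis, cost contours."""

import numpy as np
import pytest

from iterident.calibration import CalibrationProblem, OptimizerConfig
from iterident.model_core import (ConfigurationError, ExperimentDesign,
                                  MeasurementSet, NoiseSpec,
                                  StimulusProfile, predict_observables)
from iterident.practical_id import (ECCENTRICITY_CAP, SolutionCloud,
                                    cost_contours, monte_carlo_cloud,
                                    trim_and_fit, uncertainty_report)

from conftest import DECAY_GAIN, SUM_ONLY, build


def _design(times, duration=None):
    times = np.asarray(times, float)
    return ExperimentDesign("d", StimulusProfile([], duration
                                                 or float(times[-1])),
                            ["y"], {"y": times.copy()})


def _synthetic_cloud(X, names=None):
    X = np.asarray(X, float)
    names = names or [f"p{i}" for i in range(X.shape[1])]
    return SolutionCloud(X, np.zeros(X.shape[0]), names, 0, X.shape[0],
                         theta_ref=None)


class TestMonteCarloCloud:
    def test_zero_noise_replicates_recover_truth(self):
        model, space = build(DECAY_GAIN)
        scheme = [_design(np.linspace(0.3, 4.0, 8))]
        cloud = monte_carlo_cloud(model, space, scheme, ["k", "g"],
                                  theta_true=space.nominal, n_reps=10,
                                  noise_spec=NoiseSpec(0.0, 0.0),
                                  master_seed=0)
        truth = space.nominal[space.indices(["k", "g"])]
        assert cloud.n_replicates == 10
        assert np.abs(cloud.estimates / truth - 1).max() < 1e-6

    def test_cloud_sd_matches_linear_least_squares_theory(self):
        """y = k t + noise (constant sigma): the estimator sd has the
        closed form sigma / sqrt(sum t^2); 500 replicates within 10%."""
        cfg = {
            "name": "line", "states": ["x"],
            "params": [{"name": "k", "value": 2.0, "free": True,
                        "lower": 0.2, "upper": 20.0}],
            "rhs": {"x": "k"},
            "observables": {"y": {"x": 1.0}},
            "initial": {"policy": "fixed", "seed": {"x": "0"}},
        }
        model, space = build(cfg)
        times = np.linspace(0.5, 3.0, 6)
        d = _design(times)
        sigma = 0.15
        d.noise = NoiseSpec(0.0, sigma)
        cloud = monte_carlo_cloud(model, space, [d], ["k"],
                                  theta_true=space.nominal, n_reps=500,
                                  noise_spec=NoiseSpec(0.0, sigma),
                                  master_seed=3)
        theory = sigma / np.sqrt((times ** 2).sum())
        assert cloud.estimates[:, 0].std(ddof=1) == pytest.approx(
            theory, rel=0.10)

    def test_cloud_is_reproducible_from_master_seed(self):
        model, space = build(DECAY_GAIN)
        scheme = [_design(np.linspace(0.3, 4.0, 6))]
        kw = dict(theta_true=space.nominal, n_reps=8,
                  noise_spec=NoiseSpec(0.05, 0.0), master_seed=17)
        a = monte_carlo_cloud(model, space, scheme, ["k", "g"], **kw)
        b = monte_carlo_cloud(model, space, scheme, ["k", "g"], **kw)
        assert np.array_equal(a.estimates, b.estimates)

    def test_a_posteriori_mode_runs_from_data(self):
        model, space = build(DECAY_GAIN)
        d = _design(np.linspace(0.3, 4.0, 8))
        from iterident.model_core import generate_noisy_replicate
        truth = predict_observables(model, space.nominal, d)
        data = [generate_noisy_replicate(truth, NoiseSpec(0.1, 0.0),
                                         seed=2)]
        cloud = monte_carlo_cloud(model, space, [d], ["k", "g"], data=data,
                                  n_reps=25, noise_spec=NoiseSpec(0.1, 0.0),
                                  optimizer=OptimizerConfig(budget=300),
                                  master_seed=5)
        assert cloud.mode == "a_posteriori"
        assert cloud.n_replicates >= 13
        # fitted-centre cloud stays near the truth at this noise level
        truth_free = space.nominal[space.indices(["k", "g"])]
        mu = np.median(cloud.estimates, axis=0)
        assert np.abs(mu / truth_free - 1).max() < 0.5


class TestTrimAndFit:
    def test_isotropic_gaussian_cloud_has_low_eccentricity(self, rng):
        X = 1.0 + 0.01 * rng.standard_normal((1000, 3))
        fit, T = trim_and_fit(_synthetic_cloud(X))
        off = fit.pairwise_ecc[~np.eye(3, dtype=bool)]
        assert (off >= 1.0).all() and (off < 1.3).all()

    def test_perfectly_correlated_pair_is_capped_and_flagged(self, rng):
        a = 1.0 + 0.05 * rng.standard_normal(500)
        X = np.c_[a, 2.0 * a]
        fit, _ = trim_and_fit(_synthetic_cloud(X))
        assert fit.pairwise_ecc[0, 1] == ECCENTRICITY_CAP
        assert (0, 1) in fit.degenerate_pairs

    def test_trim_retains_about_ninety_percent_per_coordinate(self, rng):
        X = rng.standard_normal((2000, 1)) + 5.0
        fit, T = trim_and_fit(_synthetic_cloud(X))
        assert 0.88 <= T.shape[0] / X.shape[0] <= 0.92

    def test_degenerate_cloud_gives_zero_axes(self):
        X = np.ones((30, 2))
        fit, _ = trim_and_fit(_synthetic_cloud(X))
        assert np.allclose(fit.lengths, 0.0)

    def test_too_small_cloud_rejected(self):
        with pytest.raises(ConfigurationError):
            trim_and_fit(_synthetic_cloud(np.ones((10, 2))))

    def test_eccentricity_invariant_to_unit_rescaling(self, rng):
        a = rng.standard_normal(800)
        b = 0.6 * a + 0.3 * rng.standard_normal(800)
        X = np.c_[10.0 + a, 5.0 + b]
        f1, _ = trim_and_fit(_synthetic_cloud(X))
        X2 = X.copy()
        X2[:, 1] *= 1e3   # change of units on one coordinate
        f2, _ = trim_and_fit(_synthetic_cloud(X2))
        assert f1.pairwise_ecc[0, 1] == pytest.approx(f2.pairwise_ecc[0, 1],
                                                      rel=1e-6)


class TestUncertaintyReport:
    def test_single_repeated_point_has_zero_uncertainty(self):
        X = np.full((40, 2), 3.0)
        cloud = _synthetic_cloud(X)
        fit, _ = trim_and_fit(cloud)
        rep = uncertainty_report(cloud, fit)
        assert (rep.table.C_theta == 0).all()
        assert (rep.table.C_pct == 0).all()

    def test_delta_percent_zero_when_mean_equals_nominal(self):
        X = np.full((40, 1), 2.5)
        cloud = _synthetic_cloud(X)
        fit, _ = trim_and_fit(cloud)
        rep = uncertainty_report(cloud, fit, theta_star=np.array([2.5]))
        assert rep.table.delta_pct.iloc[0] == 0.0

    def test_report_identifies_most_eccentric_pair(self, rng):
        a = rng.standard_normal(600)
        X = np.c_[5 + a, 5 + a + 0.05 * rng.standard_normal(600),
                  5 + rng.standard_normal(600)]
        cloud = _synthetic_cloud(X, names=["u", "v", "w"])
        fit, _ = trim_and_fit(cloud)
        rep = uncertainty_report(cloud, fit)
        assert set(rep.max_ecc_pair) == {"u", "v"}
        assert rep.pseudo_volume > 0


class TestCostContours:
    def test_quadratic_toy_minimum_found_and_closed(self):
        model, space = build(DECAY_GAIN)
        d = _design(np.linspace(0.3, 4.0, 10))
        truth = predict_observables(model, space.nominal, d)
        data = MeasurementSet(d, {"y": truth.values["y"].copy()},
                              {"y": np.full(10, 0.05)})
        prob = CalibrationProblem(model, space, [data], ["k", "g"])
        res = cost_contours(prob, ("k", "g"), n_grid=21, span=2.0)
        assert res["min"] < 1e-6
        assert res["argmin"][0] == pytest.approx(0.8, rel=0.15)
        assert not res["open_ended"]

    def test_sum_only_valley_is_open_ended(self):
        model, space = build(SUM_ONLY)
        d = _design(np.linspace(0.3, 3.0, 10))
        truth = predict_observables(model, space.nominal, d)
        data = MeasurementSet(d, {"y": truth.values["y"].copy()},
                              {"y": np.full(10, 0.05)})
        prob = CalibrationProblem(model, space, [data], ["k1", "k2"])
        res = cost_contours(prob, ("k1", "k2"), n_grid=21, span=3.0)
        assert res["open_ended"]
        assert res["valley_anisotropy"] > 1.5
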