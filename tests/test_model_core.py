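"""Model representation, NF-kB instantiation, simulation and noise."""

import io

import numpy as np
import pytest
import sympy as sp

from iterident.model_core import (ConfigurationError, NoiseSpec,
                                  StimulusProfile, ExperimentDesign,
                                  generate_noisy_replicate,
                                  measurements_from_frame,
                                  measurements_to_frame, model_from_config,
                                  predict_observables, resting_state,
                                  simulate)
from iterident.nfkb import (NFKB_CONFIG, OBSERVABLES_LEE, build_nfkb_model,
                            es1_surrogate_scheme, nfkb_conserved_total)

from conftest import DECAY, build


# --- hand-typed transcription fixture: every reaction term of the NF-kB
#     right-hand side, state by state (rates per second; TR is the binary
#     TNF signal, kv the cytoplasmic/nuclear volume ratio) -----------------
NFKB_RHS_FIXTURE = {
    "IKKn": "kprod - kdeg*IKKn - TR*k1*IKKn",
    "IKKa": ("TR*k1*IKKn - k3*IKKa - TR*k2*IKKa*A20 - kdeg*IKKa "
             "- a2*IKKa*IkBa + t1*IKKa_IkBa - a3*IKKa*IkBa_NFkB "
             "+ t2*IKKa_IkBa_NFkB"),
    "IKKi": "k3*IKKa + TR*k2*IKKa*A20 - kdeg*IKKi",
    "IkBa": ("-a2*IKKa*IkBa - a1*IkBa*NFkB + c4a*IkBat - c5a*IkBa "
             "- i1a*IkBa + e1a*IkBan"),
    "IkBan": "-a1*IkBan*NFkBn + i1a*kv*IkBa - e1a*kv*IkBan",
    "IkBat": "c2a + c1a*NFkBn - c3a*IkBat",
    "IKKa_IkBa": "a2*IKKa*IkBa - t1*IKKa_IkBa",
    "IKKa_IkBa_NFkB": "a3*IKKa*IkBa_NFkB - t2*IKKa_IkBa_NFkB",
    "A20": "c4*A20t - c5*A20",
    "A20t": "c2 + c1*NFkBn - c3*A20t",
    "NFkB": "c6a*IkBa_NFkB - a1*IkBa*NFkB + t2*IKKa_IkBa_NFkB - i1*NFkB",
    "NFkBn": "i1*kv*NFkB - a1*IkBan*NFkBn",
    "IkBa_NFkB": ("a1*IkBa*NFkB - c6a*IkBa_NFkB - a3*IKKa*IkBa_NFkB "
                  "+ e2a*IkBan_NFkBn"),
    "IkBan_NFkBn": "a1*IkBan*NFkBn - e2a*kv*IkBan_NFkBn",
    "cgent": "c2c + c1c*NFkBn - c3c*cgent",
}


class TestNFkBModel:
    def test_transcription_against_fixture(self, nfkb):
        """Each equation of the built model equals the hand-typed fixture
        term by term (catching transcription typos symbolically)."""
        model, _ = nfkb
        sym = model.symbolic
        ns = {s.name: s for s in sym.x + sym.theta + sym.u}
        rhs = sym.rhs_exprs()
        for k, sname in enumerate(model.state_names):
            expected = 60 * sp.sympify(NFKB_RHS_FIXTURE[sname], locals=ns)
            assert sp.expand(rhs[k] - expected) == 0, sname

    def test_dimensions_and_free_parameters(self, nfkb):
        model, space = nfkb
        assert model.n_states == 15
        assert model.n_params == 30
        assert len(space.free_names) == 13

    def test_table_nominal_values(self, nfkb):
        _, space = nfkb
        assert space.nominal[space.index("k1")] == pytest.approx(2.5e-3)
        assert space.nominal[space.index("kv")] == 5.0
        assert not space.free_mask[space.index("kv")]
        assert space.nominal[space.index("NF")] == pytest.approx(0.06)

    def test_numba_kernels_match_symbolic(self, nfkb, rng):
        model, space = nfkb
        ref, _ = model_from_config(NFKB_CONFIG)
        for _ in range(20):
            x = rng.uniform(0, 0.3, 15)
            u = np.array([float(rng.integers(0, 2))])
            th = space.nominal * rng.uniform(0.5, 2.0, 30)
            assert np.allclose(model.rhs(x, u, th), ref.rhs(x, u, th),
                               rtol=1e-12, atol=1e-12)
            assert np.allclose(model.jac_x(x, u, th), ref.jac_x(x, u, th),
                               rtol=1e-12, atol=1e-12)
            assert np.allclose(model.jac_theta(x, u, th),
                               ref.jac_theta(x, u, th),
                               rtol=1e-12, atol=1e-12)

    def test_control_affine_consistency(self, nfkb, rng):
        """f + sum u_i g_i reproduces the rhs at 100 random points."""
        model, space = nfkb
        for _ in range(100):
            x = rng.uniform(0, 0.5, 15)
            u = np.array([rng.uniform(0, 1)])
            th = space.nominal * rng.uniform(0.3, 3.0, 30)
            recon = model.drift(x, th) + u[0] * model.control_fields(x, th)[0]
            err = np.abs(recon - model.rhs(x, u, th)).max()
            assert err < 1e-10 * max(1.0, np.abs(recon).max())


class TestRestingState:
    def test_linear_toy_matches_analytic_fixed_point(self):
        cfg = {
            "name": "lin", "states": ["x"],
            "params": [{"name": "a", "value": 2.0, "free": True},
                       {"name": "b", "value": 3.0, "free": True}],
            "rhs": {"x": "b - a*x"},
            "observables": {"y": {"x": 1.0}},
            "initial": {"policy": "resting", "seed": {"x": "0"}},
        }
        model, space = build(cfg)
        xr = resting_state(model, space.nominal)
        assert xr[0] == pytest.approx(1.5, rel=1e-9)

    def test_nfkb_resting_residual_and_inactive_ikk(self, nfkb, nfkb_rest):
        model, space = nfkb
        r = model.rhs(nfkb_rest, np.zeros(1), space.nominal)
        assert np.linalg.norm(r) < 1e-10
        assert nfkb_rest[model.state_index("IKKa")] == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_resting_state_is_stationary_over_1000_min(self, nfkb,
                                                       nfkb_rest):
        model, space = nfkb
        ts = np.linspace(0, 1000.0, 11)
        X = simulate(model, space.nominal, StimulusProfile([], 1000.0), ts,
                     x0=nfkb_rest)
        scale = np.abs(nfkb_rest) + 1e-12
        drift = np.abs(X - nfkb_rest[None, :]) / scale
        assert drift.max() < 1e-6


class TestSimulation:
    def test_unstimulated_trajectory_is_constant(self, nfkb, nfkb_rest):
        model, space = nfkb
        ts = np.linspace(0, 360, 13)
        X = simulate(model, space.nominal, StimulusProfile([], 360.0), ts,
                     x0=nfkb_rest)
        rel = np.abs(X - nfkb_rest[None, :]) / (np.abs(nfkb_rest) + 1e-12)
        assert rel.max() < 1e-6

    def test_persistent_tnf_drives_damped_oscillations(self, nfkb,
                                                       nfkb_rest):
        """Nuclear NF-kB shows at least two local maxima within 6 h of
        persistent stimulation."""
        model, space = nfkb
        ts = np.linspace(0, 360, 721)
        X = simulate(model, space.nominal, StimulusProfile.persistent(360.0),
                     ts, x0=nfkb_rest)
        nn = X[:, model.state_index("NFkBn")]
        interior = (nn[1:-1] > nn[:-2]) & (nn[1:-1] > nn[2:])
        assert interior.sum() >= 2

    @pytest.mark.parametrize("scale", [1.0, 1.7, 0.6])
    def test_total_nfkb_conserved_along_trajectories(self, nfkb, scale):
        model, space = nfkb
        th = space.nominal.copy()
        free = space.indices(space.free_names)
        th[free] = th[free] * scale
        ts = np.linspace(0, 360, 40)
        X = simulate(model, th, StimulusProfile.pulse(0, 90, 360.0), ts)
        tot = (nfkb_conserved_total(th) @ X.T).ravel()
        assert np.abs(tot - tot[0]).max() / tot[0] < 1e-6

    def test_grid_refinement_convergence(self, nfkb, nfkb_rest):
        model, space = nfkb
        d = es1_surrogate_scheme()[0]
        a = predict_observables(model, space.nominal, d, x0=nfkb_rest,
                                rtol=1e-8, atol=1e-12)
        b = predict_observables(model, space.nominal, d, x0=nfkb_rest,
                                rtol=5e-9, atol=5e-13)
        for o in d.observables:
            rel = np.abs(a.values[o] - b.values[o]) / \
                (np.abs(b.values[o]) + 1e-12)
            assert rel.max() < 1e-5


class TestObservables:
    def test_active_ikk_is_zero_before_stimulation(self, nfkb, nfkb_rest):
        model, space = nfkb
        d = es1_surrogate_scheme()[0]
        d0 = ExperimentDesign("t0", StimulusProfile.persistent(10.0),
                              ["IKKa"], {"IKKa": np.array([1e-9])})
        ms = predict_observables(model, space.nominal, d0, x0=nfkb_rest)
        assert abs(ms.values["IKKa"][0]) < 1e-8

    def test_composite_observables_are_sums_of_components(self, nfkb,
                                                          nfkb_rest):
        model, space = nfkb
        times = np.linspace(10, 240, 8)
        obs = ["IKK_total", "IKKn", "IKKa", "IKKi", "IkBa_cyt_total"]
        d = ExperimentDesign(
            "comp", StimulusProfile.persistent(240.0),
            ["IKK_total", "IKKa"], {o: times.copy()
                                    for o in ["IKK_total", "IKKa"]})
        ms = predict_observables(model, space.nominal, d, x0=nfkb_rest)
        X = simulate(model, space.nominal, d.stimulus, times, x0=nfkb_rest)
        manual = sum(X[:, model.state_index(s)]
                     for s in ("IKKn", "IKKa", "IKKi"))
        assert np.allclose(ms.values["IKK_total"], manual, rtol=1e-12)

    def test_lee_experiment_has_six_observables(self):
        lee = es1_surrogate_scheme()[0]
        assert len(lee.observables) == 6
        assert set(lee.observables) == set(OBSERVABLES_LEE)

    def test_unknown_observable_is_configuration_error(self, nfkb):
        model, _ = nfkb
        with pytest.raises(ConfigurationError):
            model.observation_matrix(["nonexistent"])


class TestNoise:
    def test_zero_noise_returns_truth_exactly(self, nfkb, nfkb_rest):
        model, space = nfkb
        d = es1_surrogate_scheme()[0]
        nl = predict_observables(model, space.nominal, d, x0=nfkb_rest)
        rep = generate_noisy_replicate(nl, NoiseSpec(0.0, 0.0), seed=3)
        for o in d.observables:
            assert np.array_equal(rep.values[o], nl.values[o])

    def test_sample_sd_matches_noise_model(self):
        """10^4 replicates of one point: empirical sd within 3% of the
        specified 10% relative level."""
        design = ExperimentDesign("one", StimulusProfile.persistent(10.0),
                                  ["y"], {"y": np.array([5.0])})
        truth = type("MS", (), {})()
        from iterident.model_core import MeasurementSet
        nl = MeasurementSet(design, {"y": np.array([2.0])},
                            {"y": np.array([0.2])})
        spec = NoiseSpec(0.1, 0.0)
        vals = np.array([
            generate_noisy_replicate(nl, spec, seed=s).values["y"][0]
            for s in range(10000)])
        ratio = vals.std(ddof=1) / (0.1 * 2.0)
        assert 0.97 < ratio < 1.03

    def test_same_seed_is_bit_identical(self, nfkb, nfkb_rest):
        model, space = nfkb
        d = es1_surrogate_scheme()[0]
        nl = predict_observables(model, space.nominal, d, x0=nfkb_rest)
        a = generate_noisy_replicate(nl, NoiseSpec(), seed=7)
        b = generate_noisy_replicate(nl, NoiseSpec(), seed=7)
        for o in d.observables:
            assert np.array_equal(a.values[o], b.values[o])

    def test_negative_noise_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            NoiseSpec(-0.1, 0.0)
        with pytest.raises(ConfigurationError):
            NoiseSpec(0.1, -1e-9)


class TestInterfaces:
    def test_measurement_csv_roundtrip_is_bit_stable(self, nfkb, nfkb_rest):
        import pandas as pd
        model, space = nfkb
        scheme = es1_surrogate_scheme()
        sets = [generate_noisy_replicate(
            predict_observables(model, space.nominal, d, x0=nfkb_rest),
            NoiseSpec(), seed=i) for i, d in enumerate(scheme)]
        df = measurements_to_frame(sets)
        buf = io.StringIO()
        df.to_csv(buf, index=False, float_format="%.17g")
        text1 = buf.getvalue()
        back = measurements_from_frame(
            pd.read_csv(io.StringIO(text1), float_precision="round_trip"),
            {d.name: d for d in scheme})
        buf2 = io.StringIO()
        measurements_to_frame(back).to_csv(buf2, index=False,
                                           float_format="%.17g")
        assert buf2.getvalue() == text1

    def test_stimulus_validation(self):
        with pytest.raises(ConfigurationError):
            StimulusProfile([10.0, 5.0], 60.0)       # not increasing
        with pytest.raises(ConfigurationError):
            StimulusProfile([0, 1, 2, 3, 4, 5], 60.0, max_pulses=2)
        s = StimulusProfile.pulse(0.0, 60.0, 360.0)
        assert s.kind == "pulse-train"
        assert s.value(30.0) == 1.0 and s.value(120.0) == 0.0
        segs = s.segments()
        assert segs[0] == (0.0, 60.0, 1.0)
        assert segs[-1][1] == 360.0

    def test_non_control_affine_config_is_rejected(self):
        bad = {
            "name": "bad", "states": ["x"], "controls": ["u"],
            "params": [{"name": "k", "value": 1.0, "free": True}],
            "rhs": {"x": "-k*x + u**2"},
            "observables": {"y": {"x": 1.0}},
            "initial": {"policy": "fixed", "seed": {"x": "1"}},
        }
        with pytest.raises(ConfigurationError):
            model_from_config(bad)
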