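"""The NF-kB regulatory module (Lipniacki-type model).

Two-compartment kinetics of the activators IKK and NF-kB, the inhibitors
A20 and IkBa and their complexes: 15 states, 30 parameters (units uM, min),
driven by the binary TNF signal T_R.  IKK cycles through neutral (IKKn),
active (IKKa) and inactive (IKKi) forms; active IKK phosphorylates IkBa and
thereby frees NF-kB, which translocates to the nucleus and upregulates
transcription of its own inhibitors IkBa and A20 (and a control gene cgen).
Nuclear/cytoplasmic transport carries the volume ratio k_v; the total NF-kB
pool (free + complexed, nuclear species weighted 1/k_v) is conserved and
equals N_F.  Concentrations are cytoplasmic-volume normalised, so
N_F = 0.06 in model units.

The declarative config below is the single source of truth; hand-written
numba kernels provide the fast numerical path and are pinned against the
symbolic definition by the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model_core import (DynamicModel, ExperimentDesign, NoiseSpec,
                         ParameterSpace, StimulusProfile, model_from_config)

__all__ = ["NFKB_CONFIG", "build_nfkb_model", "nfkb_conserved_total",
           "OBSERVABLES_LEE", "OBSERVABLES_HOFFMANN", "OBSERVABLES_ALL",
           "es1_surrogate_scheme", "ranking_schemes", "get_model"]

# Parameters flagged "To be identified" (13 of 30); the remainder are fixed.
_FREE = {"t1", "t2", "c3a", "c4a", "c5", "k1", "k2", "k3",
         "kprod", "kdeg", "i1", "e2a", "i1a"}

_PARAM_TABLE = [
    # (name, nominal)
    ("a1", 0.5), ("a2", 0.2), ("t1", 0.1), ("a3", 1.0), ("t2", 0.1),
    ("c1a", 5e-7), ("c2a", 0.0), ("c3a", 4e-4), ("c4a", 0.5), ("c5a", 1e-4),
    ("c6a", 2e-5), ("c1", 5e-7), ("c2", 0.0), ("c3", 4e-4), ("c4", 0.5),
    ("c5", 3e-4), ("k1", 2.5e-3), ("k2", 0.1), ("k3", 1.5e-3),
    ("kprod", 2.5e-5), ("kdeg", 1.25e-4), ("NF", 0.06), ("kv", 5.0),
    ("i1", 2.5e-3), ("e2a", 0.01), ("i1a", 1e-3), ("e1a", 5e-4),
    ("c1c", 5e-7), ("c2c", 0.0), ("c3c", 4e-4),
]

_STATES = ["IKKn", "IKKa", "IKKi", "IkBa", "IkBan", "IkBat",
           "IKKa_IkBa", "IKKa_IkBa_NFkB", "A20", "A20t",
           "NFkB", "NFkBn", "IkBa_NFkB", "IkBan_NFkBn", "cgent"]

NFKB_CONFIG = {
    "name": "nfkb",
    "states": _STATES,
    "controls": ["TR"],
    # Rate constants are per second (their customary units); simulations and
    # designs track time in minutes, hence the factor 60 on the whole rhs.
    "time_scale": 60.0,
    "params": [{"name": n, "value": v, "free": n in _FREE}
               for n, v in _PARAM_TABLE],
    "rhs": {
        "IKKn": "kprod - kdeg*IKKn - TR*k1*IKKn",
        "IKKa": ("TR*k1*IKKn - k3*IKKa - TR*k2*IKKa*A20 - kdeg*IKKa"
                 " - a2*IKKa*IkBa + t1*IKKa_IkBa"
                 " - a3*IKKa*IkBa_NFkB + t2*IKKa_IkBa_NFkB"),
        "IKKi": "k3*IKKa + TR*k2*IKKa*A20 - kdeg*IKKi",
        "IkBa": ("-a2*IKKa*IkBa - a1*IkBa*NFkB + c4a*IkBat - c5a*IkBa"
                 " - i1a*IkBa + e1a*IkBan"),
        "IkBan": "-a1*IkBan*NFkBn + i1a*kv*IkBa - e1a*kv*IkBan",
        "IkBat": "c2a + c1a*NFkBn - c3a*IkBat",
        "IKKa_IkBa": "a2*IKKa*IkBa - t1*IKKa_IkBa",
        "IKKa_IkBa_NFkB": "a3*IKKa*IkBa_NFkB - t2*IKKa_IkBa_NFkB",
        "A20": "c4*A20t - c5*A20",
        "A20t": "c2 + c1*NFkBn - c3*A20t",
        "NFkB": "c6a*IkBa_NFkB - a1*IkBa*NFkB + t2*IKKa_IkBa_NFkB - i1*NFkB",
        "NFkBn": "i1*kv*NFkB - a1*IkBan*NFkBn",
        "IkBa_NFkB": ("a1*IkBa*NFkB - c6a*IkBa_NFkB - a3*IKKa*IkBa_NFkB"
                      " + e2a*IkBan_NFkBn"),
        "IkBan_NFkBn": "a1*IkBan*NFkBn - e2a*kv*IkBan_NFkBn",
        "cgent": "c2c + c1c*NFkBn - c3c*cgent",
    },
    # Observables measured by the wild-type experiments: A20 mRNA, total IKK,
    # active IKK, total cytoplasmic IkBa, IkBa mRNA and free nuclear NF-kB.
    "observables": {
        "A20t": {"A20t": 1.0},
        "IKK_total": {"IKKn": 1.0, "IKKa": 1.0, "IKKi": 1.0},
        "IKKa": {"IKKa": 1.0},
        "IkBa_cyt_total": {"IkBa": 1.0, "IkBa_NFkB": 1.0},
        "IkBat": {"IkBat": 1.0},
        "NFkBn": {"NFkBn": 1.0},
    },
    # Seed state for the resting computation: neutral IKK at its production/
    # degradation balance and the whole NF-kB pool bound in cytoplasmic
    # IkBa|NF-kB complex.  Any state in the basin of the resting equilibrium
    # works; this one is inside it for the whole calibration box.
    "initial": {"policy": "resting",
                "seed": {"IKKn": "kprod/kdeg", "IkBa_NFkB": "NF"}},
}

OBSERVABLES_LEE = ["A20t", "IKK_total", "IKKa", "IkBa_cyt_total", "IkBat",
                   "NFkBn"]
OBSERVABLES_HOFFMANN = ["NFkBn", "IkBa_cyt_total"]
OBSERVABLES_ALL = OBSERVABLES_LEE


# ---------------------------------------------------------------------------
# numba kernels (fast path; pinned against the symbolic model by tests)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _rhs(x, u, th):
    a1 = th[0]; a2 = th[1]; t1 = th[2]; a3 = th[3]; t2 = th[4]
    c1a = th[5]; c2a = th[6]; c3a = th[7]; c4a = th[8]; c5a = th[9]
    c6a = th[10]; c1 = th[11]; c2 = th[12]; c3 = th[13]; c4 = th[14]
    c5 = th[15]; k1 = th[16]; k2 = th[17]; k3 = th[18]; kprod = th[19]
    kdeg = th[20]; kv = th[22]; i1 = th[23]; e2a = th[24]; i1a = th[25]
    e1a = th[26]; c1c = th[27]; c2c = th[28]; c3c = th[29]
    TR = u[0]
    dx = np.empty(15)
    dx[0] = kprod - kdeg * x[0] - TR * k1 * x[0]
    dx[1] = (TR * k1 * x[0] - k3 * x[1] - TR * k2 * x[1] * x[8]
             - kdeg * x[1] - a2 * x[1] * x[3] + t1 * x[6]
             - a3 * x[1] * x[12] + t2 * x[7])
    dx[2] = k3 * x[1] + TR * k2 * x[1] * x[8] - kdeg * x[2]
    dx[3] = (-a2 * x[1] * x[3] - a1 * x[3] * x[10] + c4a * x[5]
             - c5a * x[3] - i1a * x[3] + e1a * x[4])
    dx[4] = -a1 * x[4] * x[11] + i1a * kv * x[3] - e1a * kv * x[4]
    dx[5] = c2a + c1a * x[11] - c3a * x[5]
    dx[6] = a2 * x[1] * x[3] - t1 * x[6]
    dx[7] = a3 * x[1] * x[12] - t2 * x[7]
    dx[8] = c4 * x[9] - c5 * x[8]
    dx[9] = c2 + c1 * x[11] - c3 * x[9]
    dx[10] = c6a * x[12] - a1 * x[3] * x[10] + t2 * x[7] - i1 * x[10]
    dx[11] = i1 * kv * x[10] - a1 * x[4] * x[11]
    dx[12] = (a1 * x[3] * x[10] - c6a * x[12] - a3 * x[1] * x[12]
              + e2a * x[13])
    dx[13] = a1 * x[4] * x[11] - e2a * kv * x[13]
    dx[14] = c2c + c1c * x[11] - c3c * x[14]
    return dx * 60.0  # per-second rate constants, time tracked in minutes


@njit(cache=False)
def _jac_x(x, u, th):
    a1 = th[0]; a2 = th[1]; t1 = th[2]; a3 = th[3]; t2 = th[4]
    c1a = th[5]; c3a = th[7]; c4a = th[8]; c5a = th[9]
    c6a = th[10]; c1 = th[11]; c3 = th[13]; c4 = th[14]
    c5 = th[15]; k1 = th[16]; k2 = th[17]; k3 = th[18]
    kdeg = th[20]; kv = th[22]; i1 = th[23]; e2a = th[24]; i1a = th[25]
    e1a = th[26]; c1c = th[27]; c3c = th[29]
    TR = u[0]
    J = np.zeros((15, 15))
    J[0, 0] = -kdeg - TR * k1
    J[1, 0] = TR * k1
    J[1, 1] = -k3 - TR * k2 * x[8] - kdeg - a2 * x[3] - a3 * x[12]
    J[1, 3] = -a2 * x[1]
    J[1, 6] = t1
    J[1, 7] = t2
    J[1, 8] = -TR * k2 * x[1]
    J[1, 12] = -a3 * x[1]
    J[2, 1] = k3 + TR * k2 * x[8]
    J[2, 2] = -kdeg
    J[2, 8] = TR * k2 * x[1]
    J[3, 1] = -a2 * x[3]
    J[3, 3] = -a2 * x[1] - a1 * x[10] - c5a - i1a
    J[3, 4] = e1a
    J[3, 5] = c4a
    J[3, 10] = -a1 * x[3]
    J[4, 3] = i1a * kv
    J[4, 4] = -a1 * x[11] - e1a * kv
    J[4, 11] = -a1 * x[4]
    J[5, 5] = -c3a
    J[5, 11] = c1a
    J[6, 1] = a2 * x[3]
    J[6, 3] = a2 * x[1]
    J[6, 6] = -t1
    J[7, 1] = a3 * x[12]
    J[7, 7] = -t2
    J[7, 12] = a3 * x[1]
    J[8, 8] = -c5
    J[8, 9] = c4
    J[9, 9] = -c3
    J[9, 11] = c1
    J[10, 3] = -a1 * x[10]
    J[10, 7] = t2
    J[10, 10] = -a1 * x[3] - i1
    J[10, 12] = c6a
    J[11, 4] = -a1 * x[11]
    J[11, 10] = i1 * kv
    J[11, 11] = -a1 * x[4]
    J[12, 1] = -a3 * x[12]
    J[12, 3] = a1 * x[10]
    J[12, 10] = a1 * x[3]
    J[12, 12] = -c6a - a3 * x[1]
    J[12, 13] = e2a
    J[13, 4] = a1 * x[11]
    J[13, 11] = a1 * x[4]
    J[13, 13] = -e2a * kv
    J[14, 11] = c1c
    J[14, 14] = -c3c
    return J * 60.0


@njit(cache=False)
def _jac_theta(x, u, th):
    kv = th[22]
    i1 = th[23]; e2a = th[24]; i1a = th[25]; e1a = th[26]
    TR = u[0]
    J = np.zeros((15, 30))
    # a1
    J[3, 0] = -x[3] * x[10]
    J[4, 0] = -x[4] * x[11]
    J[10, 0] = -x[3] * x[10]
    J[11, 0] = -x[4] * x[11]
    J[12, 0] = x[3] * x[10]
    J[13, 0] = x[4] * x[11]
    # a2
    J[1, 1] = -x[1] * x[3]
    J[3, 1] = -x[1] * x[3]
    J[6, 1] = x[1] * x[3]
    # t1
    J[1, 2] = x[6]
    J[6, 2] = -x[6]
    # a3
    J[1, 3] = -x[1] * x[12]
    J[7, 3] = x[1] * x[12]
    J[12, 3] = -x[1] * x[12]
    # t2
    J[1, 4] = x[7]
    J[7, 4] = -x[7]
    J[10, 4] = x[7]
    # c1a, c2a, c3a, c4a, c5a
    J[5, 5] = x[11]
    J[5, 6] = 1.0
    J[5, 7] = -x[5]
    J[3, 8] = x[5]
    J[3, 9] = -x[3]
    # c6a
    J[10, 10] = x[12]
    J[12, 10] = -x[12]
    # c1, c2, c3, c4, c5
    J[9, 11] = x[11]
    J[9, 12] = 1.0
    J[9, 13] = -x[9]
    J[8, 14] = x[9]
    J[8, 15] = -x[8]
    # k1
    J[0, 16] = -TR * x[0]
    J[1, 16] = TR * x[0]
    # k2
    J[1, 17] = -TR * x[1] * x[8]
    J[2, 17] = TR * x[1] * x[8]
    # k3
    J[1, 18] = -x[1]
    J[2, 18] = x[1]
    # kprod
    J[0, 19] = 1.0
    # kdeg
    J[0, 20] = -x[0]
    J[1, 20] = -x[1]
    J[2, 20] = -x[2]
    # NF (21): enters only through the initial condition -> zero in the rhs
    # kv
    J[4, 22] = i1a * x[3] - e1a * x[4]
    J[11, 22] = i1 * x[10]
    J[13, 22] = -e2a * x[13]
    # i1
    J[10, 23] = -x[10]
    J[11, 23] = kv * x[10]
    # e2a
    J[12, 24] = x[13]
    J[13, 24] = -kv * x[13]
    # i1a
    J[3, 25] = -x[3]
    J[4, 25] = kv * x[3]
    # e1a
    J[3, 26] = x[4]
    J[4, 26] = -kv * x[4]
    # c1c, c2c, c3c
    J[14, 27] = x[11]
    J[14, 28] = 1.0
    J[14, 29] = -x[14]
    return J * 60.0


def nfkb_conserved_total(theta: np.ndarray) -> np.ndarray:
    """Linear conservation law: total NF-kB (cytoplasmic-volume equivalents);
    nuclear species carry weight 1/k_v."""
    kv = theta[22]
    w = np.zeros(15)
    for idx in (7, 10, 12):          # IKKa|IkBa|NFkB, NFkB, IkBa|NFkB
        w[idx] = 1.0
    for idx in (11, 13):             # NFkBn, IkBan|NFkBn
        w[idx] = 1.0 / kv
    return w.reshape(1, 15)


_CACHE: dict[str, tuple[DynamicModel, ParameterSpace]] = {}


def build_nfkb_model(bounds_scale: float = 10.0
                     ) -> tuple[DynamicModel, ParameterSpace]:
    """The NF-kB regulatory module: 15 states, 30 parameters with Table-1
    nominal values; the 13 parameters to be identified are free with default
    bounds (nominal/scale, nominal*scale)."""
    key = f"nfkb@{bounds_scale}"
    if key not in _CACHE:
        model, space = model_from_config(NFKB_CONFIG)
        model.rhs = lambda x, u, th: _rhs(np.asarray(x, float),
                                          np.asarray(u, float),
                                          np.asarray(th, float))
        model.jac_x = lambda x, u, th: _jac_x(np.asarray(x, float),
                                              np.asarray(u, float),
                                              np.asarray(th, float))
        model.jac_theta = lambda x, u, th: _jac_theta(np.asarray(x, float),
                                                      np.asarray(u, float),
                                                      np.asarray(th, float))
        model.conserved = nfkb_conserved_total
        space = space.scaled_bounds(bounds_scale)
        _CACHE[key] = (model, space)
    return _CACHE[key]


# ---------------------------------------------------------------------------
# Experimental schemes
# ---------------------------------------------------------------------------

def _equispaced(n: int, duration: float) -> np.ndarray:
    return np.linspace(duration / n, duration, n)


def es1_surrogate_scheme(noise: NoiseSpec | None = None
                         ) -> list[ExperimentDesign]:
    """Surrogate for the ES1 wild-type scheme (the exact published sampling
    schedules are not available): 15 equispaced samples over 4 h for the six
    observables under persistent TNF, and 15 equispaced samples over 6 h for
    nuclear NF-kB and total cytoplasmic IkBa under persistent and 1-h-pulse
    TNF stimulation."""
    noise = noise or NoiseSpec()
    lee = ExperimentDesign(
        name="lee_persistent",
        stimulus=StimulusProfile.persistent(240.0),
        observables=list(OBSERVABLES_LEE),
        sampling_times={o: _equispaced(15, 240.0) for o in OBSERVABLES_LEE},
        noise=noise)
    hoff_p = ExperimentDesign(
        name="hoffmann_persistent",
        stimulus=StimulusProfile.persistent(360.0),
        observables=list(OBSERVABLES_HOFFMANN),
        sampling_times={o: _equispaced(15, 360.0)
                        for o in OBSERVABLES_HOFFMANN},
        noise=noise)
    hoff_1h = ExperimentDesign(
        name="hoffmann_pulse1h",
        stimulus=StimulusProfile.pulse(0.0, 60.0, 360.0),
        observables=list(OBSERVABLES_HOFFMANN),
        sampling_times={o: _equispaced(15, 360.0)
                        for o in OBSERVABLES_HOFFMANN},
        noise=noise)
    return [lee, hoff_p, hoff_1h]


def ranking_schemes(noise: NoiseSpec | None = None) -> list[ExperimentDesign]:
    """The three wild-type stimulation schemes used for the global ranking:
    persistent TNF and 1-h / 2-h pulse-wise TNF, all six observables, 15
    equispaced samples over 6 h."""
    noise = noise or NoiseSpec()
    out = []
    for name, stim in [
            ("persistent", StimulusProfile.persistent(360.0)),
            ("pulse1h", StimulusProfile.pulse(0.0, 60.0, 360.0)),
            ("pulse2h", StimulusProfile.pulse(0.0, 120.0, 360.0))]:
        out.append(ExperimentDesign(
            name=name, stimulus=stim, observables=list(OBSERVABLES_ALL),
            sampling_times={o: _equispaced(15, 360.0)
                            for o in OBSERVABLES_ALL},
            noise=noise))
    return out


_EXTRA_MODELS: dict = {}


def register_model(name: str, builder) -> None:
    """Register a user model builder: builder(**kw) -> (model, space)."""
    _EXTRA_MODELS[name] = builder


def get_model(name: str, **kw) -> tuple[DynamicModel, ParameterSpace]:
    """Built-in model registry (plus user-registered builders)."""
    if name == "nfkb":
        return build_nfkb_model(**kw)
    if name in _EXTRA_MODELS:
        return _EXTRA_MODELS[name](**kw)
    raise KeyError(f"unknown model {name!r}")
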