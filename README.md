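# iterident

An iterative identifiability workbench for nonlinear dynamic biochemical
models, built around the question every modeller faces after writing down a
signalling pathway as ODEs: *can the unknown rate constants actually be
determined from the experiments we can do — and if not, which experiments
would fix that?*

The package implements the full loop:

1. **Structural identifiability** — power-series (Taylor / generating
   series) expansion of the observables, identifiability tableaus and an
   elimination procedure on the Jacobian rank of the series coefficients;
2. **Global parameter ranking** — importance factors
   (δ_msqr, δ_mabs, δ_mean, δ_max, δ_min) of relative sensitivities over
   Latin-hypercube samples of parameter space;
3. **Calibration** — weighted least squares
   J(θ) = Σ_{e,o,s} (ỹ−y(θ))²/σ² minimised by a seeded scatter-search +
   Gauss-Newton hybrid in log-parameter space;
4. **Practical identifiability** — Monte-Carlo replicate calibrations,
   trimmed-cloud principal-axis analysis, expected uncertainties C%,
   pairwise eccentricities (parameter correlation) and pseudo-volume;
5. **Optimal experimental design** — Fisher-information D/E-optimality
   over pulse-wise stimuli, sampling times and duration, designed
   *sequentially* against the information already collected.

The built-in case study is the NF-κB regulatory module (15 ODE states, 30
parameters, TNF stimulus; damped nuclear-NF-κB oscillations), on which the
loop demonstrates how a structurally identifiable but practically
unidentifiable problem is repaired by ranking-based parameter fixing and
E-optimal pulse experiments.  User models are declared in a small YAML/dict
config (sympy right-hand sides, linear observables); the same declaration
drives simulation, sensitivities and the symbolic structural analysis.

## Worked example

```python
import numpy as np
from iterident import (build_nfkb_model, resting_state, simulate,
                       StimulusProfile, analyze_structural_identifiability)

model, space = build_nfkb_model()          # Table of 30 nominal parameters
x0 = resting_state(model, space.nominal)   # unstimulated steady state

# persistent TNF drives damped nuclear-NF-kB oscillations
t = np.linspace(0, 360, 721)
X = simulate(model, space.nominal, StimulusProfile.persistent(360.0), t, x0=x0)
nn = X[:, model.state_index("NFkBn")]
peaks = t[1:-1][(nn[1:-1] > nn[:-2]) & (nn[1:-1] > nn[2:])]
print("NF-kBn maxima at", peaks, "min")

res = analyze_structural_identifiability(model, space, x0,
                                         method="generating", max_order=4)
print(res["rank"].rank, "of", res["rank"].n_free, "->", res["verdict"])
```

prints

```
NF-kBn maxima at [ 23.5 135.  236.  336.5] min
13 of 13 -> locally identifiable
```

— the oscillation period is ~100 min, and the generating-series Jacobian
reaches full rank at order 4: all 13 free parameters are (at least
locally) structurally identifiable, so any estimation trouble must be
*practical*, i.e. caused by the experiments and the noise.  The Taylor
tableau reduction (`method="taylor"`) pins down i1, k1, c3a and i1a from
single series coefficients.

The practical side of the story, at desk scale:

```python
from iterident import LoopConfig, run_identification_loop
kappa = ["c3a", "c4a", "c5", "k1", "k2", "k3", "kprod", "kdeg", "i1", "i1a"]
cfg = LoopConfig(model="nfkb", scheme="es1_surrogate", free_subset=kappa,
                 n_reps=60, run_ranking=False, max_iterations=2,
                 master_seed=1, oed_budget=200)
report = run_identification_loop(cfg)
for it in report.iterations:
    print(it["iteration"], round(it["worst_c_pct"], 1), round(it["max_ecc"], 1))
```

prints (first column: scheme; second: worst-case expected uncertainty C%
over the active parameters; third: largest pairwise eccentricity)

```
1 43.0 17.9
2 8.1 4.1
```

— under the baseline wild-type scheme the worst parameters carry ~40%
expected uncertainty and a strongly correlated pair; a single E-optimal
two-pulse experiment designed against the scheme's Fisher information cuts
both dramatically.

A thin CLI mirrors the library: `iterident calibrate`, `iterident oed`,
`iterident iterloop --config loop.yaml --out results/` (all byte-
reproducible for a fixed seed).

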