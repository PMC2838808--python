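# Identification-loop configuration for the NF-kB case study, desk scale.
# Run:  iterident iterloop --config examples/nfkb_loop.yaml --out results/
model: nfkb
scheme: es1_surrogate        # wild-type baseline (persistent + 1 h pulse TNF)
noise_rel: 0.10              # heteroscedastic Gaussian noise, 10% of signal
noise_floor: 1.0e-6          # absolute sd floor, observable units

run_structural: false        # power-series analysis (independent of data)
run_ranking: true            # LHS importance factors -> theta_kappa partition
ranking_n_lhs: 60

n_reps: 100                  # Monte-Carlo replicates per cloud
mc_budget: 400               # cost evaluations per warm replicate fit
freeze_delta_pct: 1.0        # freeze a parameter when |mu-theta*|/theta* < 1%
freeze_c_pct: 10.0           #   ... and its expected uncertainty C% < 10%

oed_criterion: E             # maximise the smallest FIM eigenvalue
oed_max_pulses: 2
oed_max_samples: 15
oed_duration_bounds: [120.0, 480.0]   # minutes
oed_budget: 400

max_iterations: 3
master_seed: 1
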