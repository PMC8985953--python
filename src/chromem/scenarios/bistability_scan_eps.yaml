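# Steady-state branches of the full circuit as the basal-erasure scale eps
# is swept: bistable (active + repressed) below a saddle-node, monostable
# above.  Basal inputs 0.1, all catalysis/erasure ratios 1 (no external TF
# input); assumed: none (all values stated for this regime).
variant: full
engine: ode
experiment: bifurcation
params: {alpha: 1, alpha_bar: 1, alpha_prime: 1, eps_prime: 1, mu: 1,
         mu_prime: 1, u0A: 0.1, u10R: 0.1, u20R: 0.1, D_tot: 50}
options:
  scan_param: eps
  grid: [0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6]
seed: 0
note: "eps grid assumed (log-ish spacing around the saddle-node)"
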