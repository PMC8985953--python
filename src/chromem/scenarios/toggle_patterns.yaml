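# Mutual repression of two positively autoregulated genes: stationary
# distribution of (nA of gene X, nA of gene Z).  Large p with small eps
# gives two exclusive on/off patterns; small p gives both-off.
variant: mutual_repression
engine: ssa
experiment: stationary
params: {alpha: 1, alpha_bar: 1, alpha_prime: 1, eps: 0.2, eps_prime: 1,
         mu: 1, mu_prime: 0.6, u0A: 0.1, u10R: 0.1, u20R: 0.1, D_tot: 20}
options: {horizon: 1000, reps: 30, samples_per_rep: 150,
          init: {"DA:X": 20, "D:Z": 20}}
circuit: {p_x: 5.0, p_z: 5.0}
seed: 17
note: "D_tot = 20 and p = 5 assumed (scaled-down toggle regime); horizon assumed"
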