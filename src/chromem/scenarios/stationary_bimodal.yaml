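# Empirical stationary distribution of (nA, nR) in the bimodal regime:
# slow basal erasure concentrates the mass near the fully active and fully
# repressed chromatin states.
variant: full
engine: ssa
experiment: stationary
params: {alpha: 0.2, alpha_bar: 0.2, alpha_prime: 0.2, eps: 0.19,
         eps_prime: 1, mu: 1, mu_prime: 1, u0A: 0.1, u10R: 0.1, u20R: 0.1,
         D_tot: 50}
options: {horizon: 2000, reps: 40, samples_per_rep: 200,
          init: {DA: 25, D: 25}}
seed: 7
note: "horizon/reps assumed; basal inputs 0.1 assumed (not printed for this regime)"
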