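# Reactivation latency: a silenced gene (nR = 45) under a strong activating
# input uA = 3.2; latency = first time nA reaches D_tot - 6.  Switch-like
# single-cell trajectories with highly variable latency at small mu'.
variant: full
engine: ssa
experiment: reactivation
params: {alpha: 0.2, alpha_bar: 0.2, alpha_prime: 0.2, eps: 0.24,
         eps_prime: 1, mu: 1, mu_prime: 0.1, uA: 3.2,
         u0A: 0.1, u10R: 0.1, u20R: 0.1, D_tot: 50}
options:
  init: {DA: 5, D1R: 15, D2R: 15, D12R: 15}
  reps: 100
  max_time: 2000
  margin: 6
  n_traj: 10
seed: 13
note: "split of nR=45 across the repressive species assumed equal"
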