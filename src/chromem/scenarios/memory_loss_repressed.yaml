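# Time to memory loss of the repressed state: first-passage samples from a
# mostly repressed start (nA=5, n1R=n2R=n12R=15) to nR = 6.
variant: full
engine: ssa
experiment: first_passage
params: {alpha: 0.2, alpha_bar: 0.2, alpha_prime: 0.2, eps: 0.36,
         eps_prime: 1, mu: 1, mu_prime: 1, u0A: 0.1, u10R: 0.1, u20R: 0.1,
         D_tot: 50}
options:
  init: {DA: 5, D1R: 15, D2R: 15, D12R: 15}
  target: nR
  op: le
  threshold: 6
  reps: 100
  max_time: 50000
seed: 11
note: "basal inputs and replicate count assumed"
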