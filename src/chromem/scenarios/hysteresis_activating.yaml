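# Quasi-static (uA, DA) input/output characteristic from the repressed
# state: at small eps the down-sweep keeps DA ~ 1 at uA = 0 (irreversible
# switching, i.e. memory of the activating stimulus).
variant: full
engine: ode
experiment: hysteresis
params: {alpha: 1, alpha_bar: 1, alpha_prime: 1, eps: 0.05, eps_prime: 1,
         mu: 1, mu_prime: 0.8, u0A: 0.1, u10R: 0.1, u20R: 0.1, D_tot: 50}
options:
  input: uA
  grid: [0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.3, 1.6, 2.0, 2.5, 3.0, 4.0]
  init: {DA: 0.0, D1R: 0.0, D2R: 0.0, D12R: 1.0}
seed: 0
note: "eps = 0.05 assumed (a value in the hysteretic regime); uA grid assumed"
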