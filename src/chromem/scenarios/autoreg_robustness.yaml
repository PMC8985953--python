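# Robustness of the active state to a repressive drive uR as the positive-
# autoregulation gain p_x grows: the critical uR* increases with p_x.
variant: full
engine: ode
experiment: robustness
params: {alpha: 1, alpha_bar: 1, alpha_prime: 1, eps: 0.1, eps_prime: 1,
         mu: 1, mu_prime: 0.7, u0A: 0.1, u10R: 0.1, u20R: 0.1, D_tot: 50}
options:
  uR_grid: [0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 1.4, 2.0, 2.8, 4.0]
  p_x_grid: [0.0, 0.5, 1.0, 2.0]
circuit: {u_tilde_A: 1.0}
seed: 0
note: "uR and p_x grids assumed; linear coupling with unit gain assumed"
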