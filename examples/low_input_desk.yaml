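c_x: 30.0
k_x_g: 0.5
k_x_m: 0.35
q_m: 0.9
annual_survival_min: 0.001
annual_survival_max: 0.25
u: 0.025
v: 0.025
l: 0.2
excretion_model: sigmoid
b: 200.0
b_c: 3.0
c_t: 6.0
c_b_mean: 2.0
c_b_halfwidth: 2.0
beta_shape:
- 4.0
- 4.0
starvation_days: 0
days_per_year: 365
d_s: 365
i_max: 15
reproductive_mode: iteroparous
growth:
  soma_initial_mass: 2000.0
  soma_asymptotic_mass: 9000.0
  soma_growth_rate: 0.0008
  gonad_peak_fraction: 0.2
  gonad_buildup_days: 120
  blood_fraction: 0.06
  gonad_reset_mass: 1.0
  growth_mode: growing
grid:
  c_step: 0.5
  alpha_step: 0.1
  n_input_nodes: 3
N: 500
seed: 0
c_g_init: 0.0
c_m_init: 15.0
recruits_use_raw_concentration: false
variation_measure: range
p0: 0.9812526032173138
px: 0.9962091367899787
a_g: 0.0
a_m: 0.0
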