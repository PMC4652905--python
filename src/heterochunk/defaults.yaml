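model:
  N_X: 30
  N_Y: 30
  M: 144
  tau_x: 1.0
  tau_y: 1.0
  tau_z: 1.5
  b_x: 2.0
  b_y: 0.1
  b_z: 0.0
  sigma_x: 0.005
  sigma_y: 0.01
  dt: 0.02
  floor: 0.0
  v_diag: 1.0
  w_diag: 0.8
plasticity:
  tau_P: 40.0
  C: 6.0
  tau_V: 30.0
  alpha_V: 0.05
  V_low: 0.3
  V_mid: 0.7
  V_high: 1.15
  theta_p: 4.5
  theta_d: 4.5
  tau_W: 60.0
  alpha_W: 0.05
  W_low: 0.3
  W_mid: 0.7
  W_high: 1.15
  theta_p_W: 2.0
  theta_d_W: 2.0
  tau_A: 2.0
  A_plus: 1.0
  A_minus: 1.0
  tau_A_y: 2.0
  tau_Q: 60.0
  alpha_Q: 4.0
  Q_low: 0.0
  Q_mid: 0.12
  Q_high: 0.4
  gamma_p_Q: 8.0
  gamma_d_Q: 0.8
  theta_p_Q: 0.5
  theta_d_Q: 0.5
  eps_H: 0.01
  m_H: 1.0
  tau_R: 80.0
  alpha_R: 0.3
  R_low: 0.1
  R_mid: 1.0
  R_high: 2.8
  gamma_p_R: 8.0
  gamma_d_R: 0.12
  theta_p_R: 1.0
  theta_d_R: 0.5
  learn_P: true
  learn_V: true
  learn_W: true
  learn_Q: true
  learn_R: true
stimulus:
  n_patterns: 24
  pixels_high: 6
  item_duration: 8.0
  noise_sigma: 0.0
  low_value: 0.0
  high_value: 1.0
  order: null
  noise_before_normalize: false
init:
  v_baseline: 1.05
  w_baseline: 0.9
  q_baseline: 0.2
  r_baseline: 0.45
  jitter: 0.03
  q_col_jitter: 0.3
  p_alpha: 0.015
n_epochs: 120
n_runs: 1
consolidation_time: 5.0
cue_duration: 16.0
recall_duration: 300.0
recall_every: 1
record_stride: 5
x_active_threshold: 0.5
y_active_threshold: 0.5
cr_threshold: 0.5
min_dwell: 3
seed: 0
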