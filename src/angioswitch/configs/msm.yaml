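# Reference configuration for the 8-cell lattice selection competition.
# Conditions follow the in-vivo perturbations: control (Vsink = 9),
# VEGF-inhibited (field amplitude 0.038) and flt1 knockdown (Vsink = 8).
# The early selection window (timesteps 20-60) is the first interval in
# which control tip counts plateau under these defaults.
name: msm
lattice:
  n_cells: 8
  cell_span: 4
  nz: 2
  ny: 8
  vegf_amplitude: 0.04
  vegf_y_gradient: 0.1
  sink_unit: 0.1
  vmax: 80.0
  dll4_cap: 1.0
  dll4_k: 0.25
  notch_strength: 6.0
  notch_exp: 2.0
  vm_relax: 0.12
  vm_init_frac: 0.1
  jitter: 0.05
  tip_signal_threshold: 0.14
  n_steps: 200
  n_replicates: 100
  hold_steps: 10
  window: [20, 60]
conditions:
  control:        {vegf_amplitude: null, vsink: 9.0}
  vegf_inhibited: {vegf_amplitude: 0.038, vsink: 9.0}
  flt1_kd:        {vegf_amplitude: null, vsink: 8.0}
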