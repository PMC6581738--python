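# Reference two-cell configuration for bistability / hysteresis / cusp
# analyses.  VEGF is swept on a 0-4 model-unit axis; with the intermediate
# feedback setting the quasi-static up-sweep switches the winning cell
# active at V = 2.5 and the down-sweep retains the active state to V = 1.
# vegf_bind_off and k6 were calibrated once
# (scripts/calibrate_reference.py) to place the saddle-node folds of the
# receptor+feedback subsystem at those anchors and are frozen here.
name: bifurcation
params:
  vegf_bind_on: 1.0
  vegf_bind_off: 89.558378
  dll4_prod: 1.5
  notch_bind_on: 1.0
  notch_bind_off: 1.0
  nicd_cat: 1.0
  he_prod: 1.0
  repress_gain: 8.0
  repress_exp: 2.0
  repress_site: output
  fb_prod: 1.0          # intermediate positive-feedback setting
  k6: 361.499126
  n_exp: 2.0
  deg_dll4: 1.0
  deg_nicd: 1.0
  deg_he: 1.0
  deg_p: 1.0
  receptor_total: 1.0
  notch_total: 2.0
classify:
  tip_threshold: 0.3
  inhibited_threshold: 0.1
  hold_time: 10.0
sweep:
  v_max: 4.0
  v_step: 0.05
# fb_prod values realising the three regimes of the one-parameter analysis
regimes:
  feedback_free: 0.0
  intermediate: 1.0
  very_high: 100.0
cusp:
  v_min: 0.1
  v_max: 4.0
  n_v: 40
  fb_min: 0.05
  fb_max: 100.0
  n_fb: 20
  include_zero_fb: true
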