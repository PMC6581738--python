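# Reference two-cell configuration for the paired-VEGF patterning-time
# matrices.  The VEGF axis is the low "c.u." regime (0.005-0.1); the grid
# is log-spaced so it brackets the 0.05 c.u. feedback-only boundary.
# vegf_bind_off was calibrated once (scripts/calibrate_reference.py) so
# that, without feedback, no cell pair with both inputs below ~0.049 c.u.
# can reach the tip DLL4 threshold, and is frozen here.  This
# configuration and the bifurcation one are independently calibrated VEGF
# scales; they are not meant to be interconverted.
name: matrix
params:
  vegf_bind_on: 1.0
  vegf_bind_off: 0.0818
  dll4_prod: 1.5
  notch_bind_on: 1.0
  notch_bind_off: 1.0
  nicd_cat: 1.0
  he_prod: 1.0
  repress_gain: 8.0
  repress_exp: 2.0
  repress_site: output
  fb_prod: 1.0          # feedback-on setting; the scan also runs fb_prod = 0
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
scan:
  v_min: 0.005
  v_max: 0.1
  n_grid: 20
  spacing: log
  horizon: 500.0
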