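# Reference synthetic-cohort configuration.  Control defaults are
# calibrated so the mean number of selections per vessel by 24 hpf is ~2;
# genotype variants encode direction only.
name: cohort
cohort:
  n_vessels: 1000
  genotypes: [control, dll4_kd, flt1_kd, vegfr_inhibited, tm4sf18_mut]
  timepoints: [20, 21, 22, 23, 24, 25, 26, 28, 30, 32, 34]
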