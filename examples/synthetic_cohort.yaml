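# Synthetic two-group study: control-like (CON) vs a cardiomyopathy-like group
# (DCM) with a depressed respiratory response to falling systolic pressure
# (tt_effect) and altered baroreflex ΔBBI–ΔSBP coupling (brs_effect), both
# 2 index-SD contrasts.
comparisons:
  - [DCM, CON]
simulate:
  seed: 7
  duration_s: 900.0
  n_per_group: {CON: 12, DCM: 12}
  groups:
    DCM: {tt_effect: 2.0, brs_effect: 2.0}
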