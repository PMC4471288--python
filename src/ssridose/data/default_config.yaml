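# Run configuration: the bundled published assumptions, spelled out so a
# copy of this file can be edited and passed via --config.
days: 30
resolution_h: 0.1
reference:
  drug: fluoxetine
  dose_mg: 40.0
# per-drug dose rounding increments (mg); empty = no rounding
rounding: {}
drugs:
  fluoxetine:
    model: mm
    volume_l: 1033
    ka_per_h: 0.53
    vm_ng_ml_h: 6.5
    km_ng_ml: 448
    t_half_h: 48
    tmax_h: 7
    cmax_ng_ml: 35
    ref_dose_mg: 40
    interval_h: 24
    standard_dose_mg: 40
  sertraline:
    model: linear
    volume_l: 1400
    t_half_h: 26
    tmax_h: 6.5
    interval_h: 24
    standard_dose_mg: 51.0
  citalopram:
    model: linear
    volume_l: 840
    t_half_h: 35
    tmax_h: 4
    interval_h: 24
    standard_dose_mg: 20.7
  venlafaxine:
    model: linear
    volume_l: 426
    t_half_h: 16.9
    tmax_h: 8
    interval_h: 24
    standard_dose_mg: 228.6
  paroxetine:
    model: mm_observables
    cmax_ng_ml: 17.6
    tmax_h: 6.3
    t_half_h: 16
    ref_dose_mg: 30
    interval_h: 24
    standard_dose_mg: 41.4
  fluvoxamine:
    model: mm_observables
    cmax_ng_ml: 30
    tmax_h: 6
    t_half_h: 19
    ref_dose_mg: 50
    interval_h: 12
    standard_dose_mg: 41.0
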