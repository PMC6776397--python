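# Class archetypes for the six principal cochlear-nucleus cell classes.
# Targets are the per-class mean feature profiles used by the synthetic
# cohort generator (units: mV, ms, MOhm, dimensionless, counts,
# spikes/s/nA).  A null target marks a measure that is undefined for the
# class (bushy cells fire only at onset, so their ISI CV does not exist).
# Omitted dispersions default to 0.4 x the between-class SD of the means.
classes:
  bushy:
    program: onset
    targets:
      RMP: -62.5
      tau_m: 1.29
      R_in: 27.5
      tau_h: 27.5
      BA_ratio: 0.50
      AP_peak: -27.6
      AP_halfwidth: 1.32
      AHP: -57.7
      adaptation: 0.96
      rebound: 0.33
      CV: null
      I_rate: 5.8
  planar_multipolar:
    program: regular
    targets:
      RMP: -62.7
      tau_m: 4.90
      R_in: 87.9
      tau_h: 40.0
      BA_ratio: 0.63
      AP_peak: 6.7
      AP_halfwidth: 0.26
      AHP: -69.2
      adaptation: 0.05
      rebound: 1.10
      CV: 0.05
      I_rate: 1232
  radiate_multipolar:
    program: adapting
    targets:
      RMP: -63.1
      tau_m: 2.83
      R_in: 60.1
      tau_h: 12.1
      BA_ratio: 0.39
      AP_peak: 5.9
      AP_halfwidth: 0.28
      AHP: -68.3
      adaptation: 0.21
      rebound: 1.17
      CV: 0.07
      I_rate: 1158
  pyramidal:
    program: regular
    targets:
      RMP: -68.5
      tau_m: 8.04
      R_in: 68.8
      tau_h: 51.0
      BA_ratio: 0.59
      AP_peak: 2.2
      AP_halfwidth: 0.40
      AHP: -64.6
      adaptation: 0.10
      rebound: 1.37
      CV: 0.10
      I_rate: 412
  cartwheel:
    program: bursting
    targets:
      RMP: -75.2
      tau_m: 5.25
      R_in: 79.6
      tau_h: 56.9
      BA_ratio: 0.95
      AP_peak: 2.9
      AP_halfwidth: 0.83
      AHP: -53.8
      adaptation: 0.22
      rebound: 1.37
      CV: 0.71
      I_rate: 768
  tuberculoventral:
    program: regular
    targets:
      RMP: -67.9
      tau_m: 12.71
      R_in: 155.6
      tau_h: 74.4
      BA_ratio: 0.71
      AP_peak: -6.9
      AP_halfwidth: 0.35
      AHP: -62.1
      adaptation: 0.13
      rebound: 11.41
      CV: 0.14
      I_rate: 1148
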