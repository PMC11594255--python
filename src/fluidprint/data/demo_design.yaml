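# Canonical cohort-design example.
#
# Schema:
#   biofluid:        urine | plasma | csf
#   n_per_class:     {HEALTHY: int, G12.0: int, G12.1: int}
#   effect_sizes:    {class_label: {metabolite_name: fold_change > 0}}
#                    (HEALTHY and unlisted pairs default to 1.0)
#   noise_sd:        additive spectral noise SD (intensity units)
#   log_sd:          SD of log-normal concentration variability
#   dilution_range:  [min, max] global multiplicative factor (urine only)
#   seed:            integer; the run is bit-reproducible from it
#   axis:            [ppm_min, ppm_max, n_points]
biofluid: urine
n_per_class:
  HEALTHY: 30
  G12.0: 20
  G12.1: 25
effect_sizes:
  G12.0:
    creatine: 2.2
    citrate: 0.55
    glucose: 1.5
    alanine: 1.6
    glutamine: 0.65
    lactate: 1.5
  G12.1:
    creatine: 1.5
    citrate: 0.75
    glucose: 1.2
    alanine: 1.25
    glutamine: 0.85
    lactate: 1.2
noise_sd: 0.05
log_sd: 0.25
dilution_range: [0.3, 3.0]
seed: 7
axis: [0.0, 10.0, 9000]
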