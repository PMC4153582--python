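# Pediatric growth functions (ages 4-15 years).
#
# fat_volume_L: piecewise-linear anchors (age yr -> adipose tissue volume, L),
#   flat extrapolation beyond the end anchors.
# liver_flow_mL_per_min: age bands (lo yr, hi yr, flow mL/min); the band value
#   applies to any age inside [lo, hi]; gaps between bands resolve to the
#   nearer band edge.
fat_volume_L:
  - [6.0, 3.68]
  - [10.0, 6.25]
  - [14.0, 11.49]
liver_flow_mL_per_min:
  - [4.0, 8.0, 325.0]
  - [9.0, 12.0, 665.0]
  - [13.0, 15.0, 915.0]
# The age regressions for pediatric cardiac output and brain blood flow are
# not available in machine-readable form; until transcribed from their
# sources, the defaults below fall back to adult allometric scaling (QCC)
# and the adult fraction of cardiac output (QBC).  Replace `mode` with
# `regression` and supply coefficients to override.
cardiac_output:
  mode: adult_allometric
  QCC: 15.87
brain_flow:
  mode: adult_fraction
  QBC: 0.11
# Plasma volume in children is a function of body weight in the source
# literature (not printed); defaults to the adult fraction of body weight.
plasma_volume:
  mode: adult_fraction
  VPC: 0.0435
# Fractional organ volumes whose pediatric regressions are likewise not
# machine-readable default to adult fractions (registry-overridable).
adult_fraction_volumes:
  VLC: 0.026
  VBC: 0.02
  VHC: {M: 0.0045, F: 0.0042}
  VGC: {M: 0.0007, F: 0.0027}
# Flow fractions for heart, fat and gonads in children adopt the adult
# percentages of cardiac output.
adult_fraction_flows:
  QFC: {M: 0.053, F: 0.091}
  QHC: {M: 0.038, F: 0.047}
  QGC: {M: 0.00054, F: 0.00022}
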