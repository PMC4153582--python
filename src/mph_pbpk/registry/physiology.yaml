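# Physiological parameters by population.
# QCC: cardiac output coefficient, L/h/kg^0.75.
# Flows: fraction of cardiac output.  Volumes: fraction of body weight.
# Entries with {M:, F:} are male/female pairs.
# Closures applied at load time:
#   QRC = 0.76 - QLC - QGC - QBC        QSC = 0.24 - QFC - QHC
#   VRC = 0.33 - VLC - VPC - VGC - VBC  VSC = 0.60 - VFC - VHC
adult_human:
  QCC: 15.87
  flows:
    QFC: {M: 0.053, F: 0.091}
    QLC: 0.24
    QBC: 0.11
    QHC: {M: 0.038, F: 0.047}
    QGC: {M: 0.00054, F: 0.00022}
  volumes:
    VPC: 0.0435
    VFC: {M: 0.213, F: 0.327}
    VLC: 0.026
    VBC: 0.02
    VHC: {M: 0.0045, F: 0.0042}
    VGC: {M: 0.0007, F: 0.0027}
# One set for both adult and juvenile rhesus monkeys; gonads from the
# human literature.
monkey:
  QCC: 18.96
  flows:
    QFC: 0.02
    QLC: 0.194
    QBC: 0.07
    QHC: 0.055
    QGC: {M: 0.00054, F: 0.00022}
  volumes:
    VPC: 0.0627
    VFC: {M: 0.179, F: 0.199}
    VLC: 0.03
    VBC: 0.018
    VHC: 0.0037
    VGC: {M: 0.0007, F: 0.0027}
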