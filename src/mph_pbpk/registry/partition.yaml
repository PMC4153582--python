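# Tissue:plasma partition coefficients for methylphenidate (dimensionless).
# Derived from tissue composition (liver/brain/heart/rich/slow from monkey
# tissues, fat/gonads from rat); shared across all populations.
Pfat: 1.79
Pbrain: 6.07
Prich: 5.66
Pslow: 2.47
Pgonads: 3.12
Pheart: 2.19
Pliver: 5.66
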