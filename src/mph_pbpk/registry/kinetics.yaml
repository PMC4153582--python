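# Chemical-specific model parameters per population and dosing route.
# Units:
#   Kmliver      ug/L          Michaelis constant, hepatic CES1 hydrolysis
#   VmaxliverC   ug/h/kg^0.75  maximum hepatic hydrolysis velocity coefficient
#   KmetC        L/h/kg^0.75   hepatic oxidation clearance coefficient
#   GEC          1/h/kg^-0.25  gastric emptying coefficient (oral only)
#   K3C          1/h/kg^-0.25  oral uptake, small intestine -> liver (oral only)
#   K5C          1/h/kg^0.75   gut metabolism coefficient (oral only)
#   F            -             fraction of gut metabolism yielding RA
#   VbodyC       L/kg          RA distribution volume coefficient
#   Ku_RAC       L/h/kg^0.75   RA urinary clearance coefficient
adult_human:
  iv:
    d: {Kmliver: 27600, VmaxliverC: 38000, KmetC: 0.7, VbodyC: 0.600, Ku_RAC: 0.305}
    l: {Kmliver: 10172, VmaxliverC: 90000, KmetC: 0.7, VbodyC: 0.600, Ku_RAC: 0.168}
  oral:
    d: {Kmliver: 27600, VmaxliverC: 38000, KmetC: 0.7, GEC: 3.5, K3C: 1.293,
        K5C: 0.042, F: 0.8, VbodyC: 0.600, Ku_RAC: 0.305}
    l: {Kmliver: 10172, VmaxliverC: 90000, KmetC: 0.7, GEC: 3.5, K3C: 1.293,
        K5C: 1.426, F: 0.8, VbodyC: 0.600, Ku_RAC: 0.168}
# Children: adult chemical parameters except K5C for l-MPH (reduced ~14-fold)
# and the RA distribution volume (pediatric total body water).
child:
  oral:
    d: {Kmliver: 27600, VmaxliverC: 38000, KmetC: 0.7, GEC: 3.5, K3C: 1.293,
        K5C: 0.042, F: 0.8, VbodyC: 0.572, Ku_RAC: 0.305}
    l: {Kmliver: 10172, VmaxliverC: 90000, KmetC: 0.7, GEC: 3.5, K3C: 1.293,
        K5C: 0.1, F: 0.8, VbodyC: 0.572, Ku_RAC: 0.168}
# Adult monkeys: adult-human hepatic parameters; gut metabolism 25x the
# adult-human values; monkey gastric emptying and total body water.
adult_monkey:
  iv:
    d: {Kmliver: 27600, VmaxliverC: 38000, KmetC: 0.7, VbodyC: 0.693, Ku_RAC: 0.305}
    l: {Kmliver: 10172, VmaxliverC: 90000, KmetC: 0.7, VbodyC: 0.693, Ku_RAC: 0.168}
  oral:
    d: {Kmliver: 27600, VmaxliverC: 38000, KmetC: 0.7, GEC: 2.34, K3C: 1.293,
        K5C: 1.05, F: 0.8, VbodyC: 0.693, Ku_RAC: 0.305}
    l: {Kmliver: 10172, VmaxliverC: 90000, KmetC: 0.7, GEC: 2.34, K3C: 1.293,
        K5C: 35.65, F: 0.8, VbodyC: 0.693, Ku_RAC: 0.168}
# Juvenile monkeys: hepatic hydrolysis ~10x and oxidation 100x the adult-monkey
# values; no gut metabolism (K5C = 0).
juvenile_monkey:
  iv:
    d: {Kmliver: 27600, VmaxliverC: 350000, KmetC: 70, VbodyC: 0.693, Ku_RAC: 0.305}
    l: {Kmliver: 10172, VmaxliverC: 700000, KmetC: 70, VbodyC: 0.693, Ku_RAC: 0.168}
  oral:
    d: {Kmliver: 27600, VmaxliverC: 350000, KmetC: 70, GEC: 2.34, K3C: 1.293,
        K5C: 0.0, F: 0.8, VbodyC: 0.693, Ku_RAC: 0.305}
    l: {Kmliver: 10172, VmaxliverC: 700000, KmetC: 70, GEC: 2.34, K3C: 1.293,
        K5C: 0.0, F: 0.8, VbodyC: 0.693, Ku_RAC: 0.168}
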