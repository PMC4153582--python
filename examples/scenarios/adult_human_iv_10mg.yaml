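# Adult-human model calibration route: single 10 mg iv bolus.
population: {species: human, age_class: adult, sex: M, route: iv, BW: 70}
schedule: {route: iv, dose: 10, dose_unit: mg,
           times_of_day: [0], days: daily, duration_days: 1}
t_end: 96
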