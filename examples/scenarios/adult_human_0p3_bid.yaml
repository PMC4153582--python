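# 70-kg adult human: 0.3 mg/kg orally, twice a day 4 h apart, daily, one week.
population: {species: human, age_class: adult, sex: M, route: oral, BW: 70}
schedule: {route: oral, dose: 0.3, dose_unit: mg/kg,
           times_of_day: [0, 4], days: daily, duration_days: 7}
t_end: 168
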