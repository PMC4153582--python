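# Juvenile rhesus toxicity-study schedule: 2.5 mg/kg orally, twice a day
# 4 h apart, Monday-Friday, for one week.
population: {species: rhesus, age_class: juvenile, sex: M, route: oral, BW: 4.0}
schedule: {route: oral, dose: 2.5, dose_unit: mg/kg,
           times_of_day: [0, 4], days: weekdays, duration_days: 7}
t_end: 168
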