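# SyntheticParams overrides for `survey-power synth --params ...`.
# Omitted keys keep the calibrated package defaults.

years: [2015, 2016, 2017, 2018]
n_sites: 2
rain_day_prob: 0.22
dropout_day_prob: 0.03
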