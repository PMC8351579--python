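# Full pipeline on a shipped synthetic deployment.
# Swap the `synthetic` block for an `inputs` block of CSV paths to run on
# field data:
#   inputs:
#     intervals: data/intervals.csv
#     environment: data/environment.csv
#     moon: data/moon.csv

seed: 1
synthetic: {}            # default SyntheticParams: 4 years, 2 sites
scenarios:
  - random
  - usfws
  - optimized
durations_min: [5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60]
permutations: 1000
mode: contiguous
optimize:
  variables: [temp_c, cum_precip_24h, pressure_change_24h]
  min_dates: 30
  top_n: 20
  resolution: 25
plots: false
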