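# Absorbed-iron requirement table template (synthetic example values).
# Columns: percentile strictly in (0, 100); requirement_mg_d non-negative,
# non-decreasing. Coarse grids are interpolated to half-percentiles at load.
# Replace the values with a published percentile table for real analyses.
percentile,requirement_mg_d
2.5,0.45
5,0.55
10,0.70
25,0.90
50,1.30
75,1.80
90,2.40
95,2.80
97.5,3.20
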