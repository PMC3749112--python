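k_surface_metabolic: 14.8
k_surface_structural: 3.9
k_active: 7.3
k_slow: 0.2
k_passive: 0.0045
resp_surface_metabolic: 0.55
resp_surface_structural: 0.45
resp_active: 0.55
resp_slow: 0.45
resp_passive: 0.55
cn_active: 11.0
cn_slow: 16.0
cn_passive: 8.0
cn_structural: 150.0
fm_intercept: 0.85
fm_slope: 0.013
q10: 2.0
t_ref: 20.0
k_nit: 0.1
f_n2o_nit: 0.02
wfps_denit_threshold: 0.6
k_denit: 0.08
denit_labile_half_sat: 300.0
k_ch4_ox: 0.0013
enteric_ef: 90.0
no3_mobility: 0.3
immob_frac: 0.5
cultivation_multiplier: 1.6
cultivation_days: 30
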