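name: energy_cane
gdd_base: 10.0
gdd_emergence: 150.0
gdd_senescence: 5500.0
max_daily_npp: 26.0
alloc_stem: 0.4
alloc_leaf: 0.38
alloc_root: 0.22
min_cn_leaf: 22.1
max_cn_leaf: 70.0
min_cn_stem: 30.5
max_cn_stem: 160.0
cn_root: 110.0
tissue_c_frac_leaf: 0.4368
tissue_c_frac_stem: 0.4118
n_fixation_rate: 0.0
temp_opt: 30.0
temp_width: 10.0
root_resp_frac: 0.25
leaf_turnover: 0.003
senescent_turnover: 0.01
dead_fall_rate: 0.01
root_turnover: 0.0025
n_resorption_frac: 0.5
lignin_frac_leaf: 0.1
lignin_frac_stem: 0.15
lignin_frac_root: 0.12
lai_ramp_c: 120.0
n_reserve_cap: 12.0
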