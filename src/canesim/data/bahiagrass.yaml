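name: bahiagrass
gdd_base: 10.0
gdd_emergence: 100.0
gdd_senescence: 1000000000.0
max_daily_npp: 5.0
alloc_stem: 0.1
alloc_leaf: 0.45
alloc_root: 0.45
min_cn_leaf: 25.0
max_cn_leaf: 60.0
min_cn_stem: 40.0
max_cn_stem: 90.0
cn_root: 70.0
tissue_c_frac_leaf: 0.42
tissue_c_frac_stem: 0.42
n_fixation_rate: 0.0
temp_opt: 30.0
temp_width: 10.0
root_resp_frac: 0.25
leaf_turnover: 0.004
senescent_turnover: 0.01
dead_fall_rate: 0.008
root_turnover: 0.003
n_resorption_frac: 0.4
lignin_frac_leaf: 0.08
lignin_frac_stem: 0.1
lignin_frac_root: 0.15
lai_ramp_c: 80.0
stem_turnover: 0.004
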