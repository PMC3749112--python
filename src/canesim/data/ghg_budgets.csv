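# Published 15-year cumulative budgets for the four scenario columns
# (pasture / energy cane on Spodosols and Histosols) and the printed
# energy-cane-minus-pasture differences.  SOC rows are end-of-phase stocks
# (g C m-2 to 1 m); flux rows are 15-year sums; CH4, N2O and total system C
# flux are g CO2eq m-2, others g C or g N m-2.
variable,spodosol_pasture,spodosol_cane,spodosol_delta,histosol_pasture,histosol_cane,histosol_delta
soc,2736,2513,-224,16087,10373,-5715
n_mineralization,134,203,69,216,293,77
heterotrophic_respiration,3130,2913,-218,2413,5715,3302
total_soil_co2,8148,8993,845,8111,11540,3429
ch4,2980,-33,-3013,2958,-46,-3004
n2o,214,649,435,6713,1742,-4970
total_system_c,-1159,-2812,-1653,-1367,924,2291
total_ghg,2035,-2196,-4231,8304,2620,-5684
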