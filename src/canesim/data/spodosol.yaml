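# Spodosol (sandy, nutrient-poor; Arenic Alaquods) default profile.
# Composition from the measured site profile; bulk density, water-retention
# and texture are NRCS-typical values for these Florida sands.
soil_type: spodosol
layers:
  - top_depth: 0.0
    bottom_depth: 30.0
    bulk_density: 1.45
    c_frac: 0.0077
    n_frac: 0.0004
    field_capacity: 0.17
    wilting_point: 0.05
    saturation: 0.40
    sand: 0.92
    silt: 0.05
    clay: 0.03
  - top_depth: 30.0
    bottom_depth: 100.0
    bulk_density: 1.55
    c_frac: 0.0036
    n_frac: 0.0002
    field_capacity: 0.15
    wilting_point: 0.04
    saturation: 0.38
    sand: 0.92
    silt: 0.05
    clay: 0.03
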