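# Histosol (drained organic muck; Histic Glossaqualfs) default profile.
# Composition is uniform with depth (7.77 %C, 0.50 %N); bulk density and
# water retention are NRCS-typical for Florida mucks.
soil_type: histosol
layers:
  - top_depth: 0.0
    bottom_depth: 100.0
    bulk_density: 0.40
    c_frac: 0.0777
    n_frac: 0.0050
    field_capacity: 0.55
    wilting_point: 0.15
    saturation: 0.80
    sand: 0.30
    silt: 0.40
    clay: 0.30
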