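{
  "compartments": [
    {"id": "POC", "volume_uL": 300.0, "role": "organoid-chamber"},
    {"id": "CC_P", "volume_uL": 50.0, "role": "channel"},
    {"id": "CC_L", "volume_uL": 50.0, "role": "channel"},
    {"id": "LOOP", "volume_uL": 500.0, "role": "tubing"},
    {"id": "LOC", "volume_uL": 300.0, "role": "organoid-chamber"}
  ],
  "convective_edges": [
    {"source": "LOOP", "target": "CC_P"},
    {"source": "CC_P", "target": "CC_L"},
    {"source": "CC_L", "target": "LOOP"}
  ],
  "membrane_interfaces": [
    {
      "pair": ["POC", "CC_P"],
      "membrane": {
        "pore_size_um": 1.0,
        "porosity": 0.8,
        "darcy_permeability_m2": 2.5e-14,
        "thickness_um": 50.0,
        "exchange_area_cm2": 0.15,
        "tortuosity": 1.0
      }
    },
    {
      "pair": ["LOC", "CC_L"],
      "membrane": {
        "pore_size_um": 1.0,
        "porosity": 0.8,
        "darcy_permeability_m2": 2.5e-14,
        "thickness_um": 50.0,
        "exchange_area_cm2": 0.15,
        "tortuosity": 1.0
      }
    }
  ],
  "channel_paths": [
    {"pair": ["CC_P", "CC_L"], "cross_section_cm2": 0.21, "path_length_cm": 0.08},
    {"pair": ["LOOP", "CC_P"], "cross_section_cm2": 0.21, "path_length_cm": 0.24}
  ],
  "fluid": {"density_kg_m3": 1030.0, "viscosity_pa_s": 0.0025},
  "shear_fluid": {"density_kg_m3": 1000.0, "viscosity_pa_s": 0.001},
  "channel": {"width_cm": 0.7, "height_cm": 0.3, "length_cm": 4.5},
  "flow": {"rate_uL_min": 600.0, "enabled": true},
  "surrogates": {"insulin": "dextran_4k", "feta": "dextran_70k"}
}
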