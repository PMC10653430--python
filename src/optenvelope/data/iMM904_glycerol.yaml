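# Example run configuration: S. cerevisiae iMM904, aerobic glycerol production.
model_path: src/optenvelope/data/iMM904.json
model_format: json
biomass_id: BIOMASS_SC5_notrace
product_id: EX_glyc_e
maintenance_ids: [ATPM]
diffusion_transport_ids: [CO2t, O2t, H2Ot, NH4t, CO2tm, O2tm, H2Otm]
target_fraction: 0.03
n_mid: 15
max_knockouts: 10
n_points: 100
molecular_weight: 0.09209     # glycerol, g/mmol
substrate_weight: 0.18016
medium:
  substrate_exchange: EX_glc__D_e
  substrate_uptake: 10.0
  free_exchanges: auto-inorganic
  aerobic: true
  # anaerobic runs delete cytochrome c oxidase instead of closing oxygen:
  # aerobic: false
  # anaerobic_deletions: [CYOOm]
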