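# Example run configuration: E. coli iJR904, aerobic acetate production.
# Fetch the model first:  python scripts/fetch_models.py
model_path: src/optenvelope/data/iJR904.json
model_format: json
biomass_id: BIOMASS_Ecoli
product_id: EX_ac_e
maintenance_ids: [ATPM]
# diffusion-based protein-free transports exempt from the activity indicator;
# judgement-call default, edit per model
diffusion_transport_ids: [CO2t, O2t, H2Ot, NH4t]
target_fraction: 0.03
n_mid: 15
max_knockouts: 10
n_points: 100
molecular_weight: 0.06005     # acetate, g/mmol
substrate_weight: 0.18016     # glucose, g/mmol
medium:
  substrate_exchange: EX_glc__D_e
  substrate_uptake: 10.0
  free_exchanges: auto-inorganic   # NH4, H2O, SO4, O2, H+, Pi, inorganic ions
  aerobic: true
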