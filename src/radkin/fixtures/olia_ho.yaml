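# Olivetolic acid + hydroxyl radical (HO) in pentyl ethanoate and water.
# Transcribed published kinetics table for this compound/radical pair.
# Diffusion-limited phenolic FHT channels use the printed diffusion
# constants as medium overrides.  The water RAF fixed rate is back-computed
# from the printed weighted rate (1.65e7 = f * k_app with f = 0.9977).
schema: 1
compound: olivetolic acid
acid_base:
  pka_values: [4.4, 10.3]
  state_labels: [neutral, monoanion, dianion]
states:
  - {label: neutral, charge: 0, mole_fraction: 0.0010}
  - {label: monoanion, charge: -1, mole_fraction: 0.9977}
  - {label: dianion, charge: -2, mole_fraction: 0.0013}
media:
  - name: water
    is_aqueous: true
    ph: 7.4
    viscosity: 8.91e-4
    diffusion_limit_override: {HO: 2.30e+9}
  - name: pentyl ethanoate
    is_aqueous: false
    viscosity: 8.62e-4
    diffusion_limit_override: {HO: 2.60e+9}
channels:
  - {mechanism: FHT, site: 1OH, radical: HO, medium: pentyl ethanoate,
     species_state: neutral, barrierless: true}
  - {mechanism: FHT, site: 3OH, radical: HO, medium: pentyl ethanoate,
     species_state: neutral, barrierless: true}
  - {mechanism: FHT, site: 7CH, radical: HO, medium: pentyl ethanoate,
     species_state: neutral, activation_free_energy: 6.1, tunneling: 0.3,
     fixed_rate: 5.40e+7}
  - {mechanism: RAF, site: C1-C6, radical: HO, medium: pentyl ethanoate,
     species_state: neutral, fixed_rate: 1.04e+8}
  - {mechanism: FHT, site: 1OH, radical: HO, medium: water,
     species_state: monoanion, barrierless: true}
  - {mechanism: FHT, site: 3OH, radical: HO, medium: water,
     species_state: monoanion, barrierless: true}
  - {mechanism: FHT, site: 7CH, radical: HO, medium: water,
     species_state: monoanion, activation_free_energy: 4.5, tunneling: 0.0,
     fixed_rate: 9.1e+7}
  - {mechanism: SET, site: mol, radical: HO, medium: water,
     species_state: neutral, fixed_rate: 0.0}
  - {mechanism: SET, site: mol, radical: HO, medium: water,
     species_state: monoanion, fixed_rate: 0.0}
  # Reaction free energy back-solved from the printed Marcus barrier
  # (0.2 kcal/mol) and reorganization energy (21.2 kcal/mol).
  - {mechanism: SET, site: mol, radical: HO, medium: water,
     species_state: dianion, activation_free_energy: 0.2,
     marcus: {reorganization_energy: 21.2, reaction_free_energy: -17.08},
     fixed_rate: 1.50e+9}
  - {mechanism: RAF, site: C1-C6, radical: HO, medium: water,
     species_state: monoanion, fixed_rate: 1.6538e+7}
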