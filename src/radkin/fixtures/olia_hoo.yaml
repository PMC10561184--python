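# Olivetolic acid + hydroperoxyl radical (HOO) in pentyl ethanoate and water.
# Transcribed published kinetics table for this compound/radical pair.
# Known inconsistency in the source table: the dianion SET row prints
# k_f = 1.87e6 while f * k_app = 0.0013 * 1.20e9 = 1.56e6; this fixture
# carries the printed inputs (f, k_app) and the pipeline reports the
# self-consistent weighted rate and overall rate (1.56e6).
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
    diffusion_limit_override: {HOO: 1.20e+9}
  - name: pentyl ethanoate
    is_aqueous: false
    viscosity: 8.62e-4
channels:
  - {mechanism: FHT, site: 7CH, radical: HOO, medium: pentyl ethanoate,
     species_state: neutral, activation_free_energy: 21.4, tunneling: 66.9,
     fixed_rate: 8.70e-2}
  - {mechanism: FHT, site: 7CH, radical: HOO, medium: water,
     species_state: monoanion, activation_free_energy: 16.3, tunneling: 33.2,
     fixed_rate: 2.50e+2}
  - {mechanism: SET, site: mol, radical: HOO, medium: water,
     species_state: neutral, fixed_rate: 0.0}
  - {mechanism: SET, site: mol, radical: HOO, medium: water,
     species_state: monoanion, fixed_rate: 0.0}
  # Reaction free energy back-solved from the printed Marcus barrier
  # (1.5 kcal/mol) and reorganization energy (2.0 kcal/mol).
  - {mechanism: SET, site: mol, radical: HOO, medium: water,
     species_state: dianion, activation_free_energy: 1.5,
     marcus: {reorganization_energy: 2.0, reaction_free_energy: 1.4641},
     fixed_rate: 1.20e+9}
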