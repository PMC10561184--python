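# Olivetol + hydroperoxyl radical (HOO) in pentyl ethanoate and water.
# Transcribed published kinetics table for this compound/radical pair.
# Printed apparent rates are carried as fixed_rate so the "printed" rate
# policy reproduces the table arithmetic exactly; barriers and tunneling
# coefficients are carried alongside for recomputation.
# The water diffusion-limit override for HOO was back-solved from the
# printed (thermal, apparent) SET pair via the Collins-Kimball relation.
schema: 1
compound: olivetol
acid_base:
  pka_values: [9.9]
  state_labels: [neutral, monoanion]
states:
  - {label: neutral, charge: 0, mole_fraction: 0.9968}
  - {label: monoanion, charge: -1, mole_fraction: 0.0032}
media:
  - name: water
    is_aqueous: true
    ph: 7.4
    viscosity: 8.91e-4
    diffusion_limit_override: {HOO: 1.81e+9}
  - name: pentyl ethanoate
    is_aqueous: false
    viscosity: 8.62e-4
channels:
  - {mechanism: FHT, site: 1OH, radical: HOO, medium: pentyl ethanoate,
     species_state: neutral, activation_free_energy: 19.1, tunneling: 145.8,
     fixed_rate: 9.60e+0}
  - {mechanism: FHT, site: 3OH, radical: HOO, medium: pentyl ethanoate,
     species_state: neutral, activation_free_energy: 19.1, tunneling: 145.8,
     fixed_rate: 9.60e+0}
  - {mechanism: FHT, site: 7CH, radical: HOO, medium: pentyl ethanoate,
     species_state: neutral, activation_free_energy: 22.1, tunneling: 55.2,
     fixed_rate: 2.30e-2}
  # SET from the undissociated phenol is not feasible; the table prints no rate.
  - {mechanism: SET, site: mol, radical: HOO, medium: water,
     species_state: neutral, fixed_rate: 0.0}
  # Reaction free energy of the phenolate SET back-solved from the printed
  # Marcus barrier (1.4 kcal/mol) and reorganization energy (1.8 kcal/mol).
  - {mechanism: SET, site: mol, radical: HOO, medium: water,
     species_state: monoanion, activation_free_energy: 1.4,
     marcus: {reorganization_energy: 1.8, reaction_free_energy: 1.3748},
     fixed_rate: 1.80e+9}
  - {mechanism: FHT, site: 1OH, radical: HOO, medium: water,
     species_state: neutral, activation_free_energy: 18.8, tunneling: 2476.9,
     fixed_rate: 2.70e+2}
  - {mechanism: FHT, site: 3OH, radical: HOO, medium: water,
     species_state: neutral, activation_free_energy: 18.8, tunneling: 2476.9,
     fixed_rate: 2.70e+2}
  - {mechanism: FHT, site: 7CH, radical: HOO, medium: water,
     species_state: neutral, activation_free_energy: 19.8, tunneling: 47.3,
     fixed_rate: 9.40e-1}
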