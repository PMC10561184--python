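# Olivetol + hydroxyl radical (HO) in pentyl ethanoate and water.
# Transcribed published kinetics table for this compound/radical pair.
# The phenolic FHT channels proceed at the diffusion limit; the printed
# diffusion constants (2.60e9 in pentyl ethanoate, 2.30e9 in water) are
# carried as per-radical medium overrides because the underlying radii are
# not published.  The water RAF fixed rate is back-computed from the
# printed weighted rate (4.48e7 = f * k_app with f = 0.9968).
# The 7CH tunneling coefficient in water is printed as 0.0 (a value that
# merely rounds to zero); it is deliberately kept here to exercise the
# ingestion rule that maps it to "absent".
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
     species_state: neutral, activation_free_energy: 6.0, tunneling: 0.6,
     fixed_rate: 1.60e+8}
  # Aggregate radical-adduct-formation rate over the ring positions C1-C6.
  - {mechanism: RAF, site: C1-C6, radical: HO, medium: pentyl ethanoate,
     species_state: neutral, fixed_rate: 5.81e+7}
  - {mechanism: SET, site: mol, radical: HO, medium: water,
     species_state: neutral, fixed_rate: 0.0}
  # Reaction free energy back-solved from the printed Marcus barrier
  # (0.1 kcal/mol) and reorganization energy (20.2 kcal/mol).
  - {mechanism: SET, site: mol, radical: HO, medium: water,
     species_state: monoanion, activation_free_energy: 0.1,
     marcus: {reorganization_energy: 20.2, reaction_free_energy: -17.358},
     fixed_rate: 2.10e+9}
  - {mechanism: FHT, site: 1OH, radical: HO, medium: water,
     species_state: neutral, barrierless: true}
  - {mechanism: FHT, site: 3OH, radical: HO, medium: water,
     species_state: neutral, barrierless: true}
  - {mechanism: FHT, site: 7CH, radical: HO, medium: water,
     species_state: neutral, activation_free_energy: 4.3, tunneling: 0.0,
     fixed_rate: 9.20e+7}
  - {mechanism: RAF, site: C1-C6, radical: HO, medium: water,
     species_state: neutral, fixed_rate: 4.4944e+7}
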