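# Copper(II) chelation by the olivetolic-acid monoanion and pro-oxidant
# single-electron-transfer kinetics of the resulting complexes with
# physiological reductants (superoxide, ascorbate).
# Transcribed published complexation free energies and redox table.
# printed_* fields are the published values kept for regression checks;
# the aqueous diffusion limit for each redox pair is not published and is
# back-solved at load time from the printed (k, k_app) pair via the
# Collins-Kimball relation (all fall near 4e9 M^-1 s^-1).
schema: 1
compound: olivetolic acid
metal: Cu2+
metal_charge: 2
# Only the monoanion is chelation-active; its physiological-pH fraction.
monoanion_fraction: 0.9977
complexation:
  - {complex: monodentate, denticity: mono, delta_g: -9.2, printed_constant: 5.39e+6}
  - {complex: bidentate, denticity: bi, delta_g: -12.3, printed_constant: 1.10e+9}
redox:
  - {complex: aquacomplex, reductant: superoxide, lambda: 31.7, dg_r: -14.9,
     printed_dg_act: 2.2, printed_k: 1.45e+11, printed_k_app: 3.75e+9}
  - {complex: monodentate, reductant: superoxide, lambda: 37.9, dg_r: -23.4,
     printed_dg_act: 1.4, printed_k: 6.01e+11, printed_k_app: 4.12e+9}
  - {complex: bidentate, reductant: superoxide, lambda: 29.0, dg_r: -20.5,
     printed_dg_act: 0.6, printed_k: 2.19e+12, printed_k_app: 4.47e+9}
  - {complex: aquacomplex, reductant: ascorbate, lambda: 26.8, dg_r: -0.5,
     printed_dg_act: 6.4, printed_k: 1.18e+8, printed_k_app: 1.15e+8}
  - {complex: monodentate, reductant: ascorbate, lambda: 19.4, dg_r: -9.0,
     printed_dg_act: 1.4, printed_k: 5.89e+11, printed_k_app: 3.78e+9}
  - {complex: bidentate, reductant: ascorbate, lambda: 22.8, dg_r: -27.4,
     printed_dg_act: 0.2, printed_k: 4.18e+12, printed_k_app: 4.35e+9}
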