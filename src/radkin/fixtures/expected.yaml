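# Expected pipeline outputs for the transcribed fixtures (regression values).
# overall rates in M^-1 s^-1; branching ratios in percent, rounded integers;
# speciation percentages rounded half-up to two decimals.
# olia_hoo in water: the source table prints 1.87e6, which is inconsistent
# with its own printed inputs (f * k_app = 0.0013 * 1.20e9 = 1.56e6); the
# self-consistent value is expected here.
overall_rates:
  oli_hoo:
    pentyl ethanoate: 1.92e+1
    water: 5.76e+6
  olia_hoo:
    pentyl ethanoate: 8.70e-2
    water: 1.56e+6
  oli_ho:
    pentyl ethanoate: 5.42e+9
    water: 4.73e+9
  olia_ho:
    pentyl ethanoate: 5.36e+9
    water: 4.70e+9
branching:
  oli_hoo:
    pentyl ethanoate: [50, 50, 0]
  olia_hoo:
    pentyl ethanoate: [100]
  oli_ho:
    pentyl ethanoate: [48, 48, 3, 1]
speciation:
  oli:
    ph: 7.4
    percents: [99.68, 0.32]
  olia:
    ph: 7.4
    percents: [0.10, 99.77, 0.13]
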