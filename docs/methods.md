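# Methods

## Scope and assumptions

`radkin` is a post-processing layer: it starts from already-computed
thermochemical scalars (activation free energies, reorganization energies,
pKa values, complexation free energies, in kcal/mol throughout) and derives
rate constants and equilibrium constants.  It performs no electronic
structure: geometries, frequencies, solvation energies and vertical gaps
are inputs.  The kinetic model is conventional transition state theory with
a separable 1-D tunneling correction — no variational effects, no
multidimensional or small-curvature tunneling, no anharmonicity.  Electron
transfers are treated as outer-sphere and non-adiabatic only insofar as the
Marcus quadratic barrier applies; the prefactor is the universal k_B T/h.
Speciation is macroscopic: one pKa ladder per compound, no site-resolved
tautomers.  Reported branching ratios are instantaneous flux fractions, not
time-evolved product distributions.

Energies stay in kcal/mol from file to formula; conversion to SI happens
only inside the rate and tunneling evaluators.  Constants come from
`scipy.constants` (R·T = 0.59248 kcal/mol and k_B T/h = 6.2124×10¹² s⁻¹ at
298.15 K).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| temperature | 298.15 | K | standard condition for every reported rate |
| pH | 7.4 | — | physiological; reproduces the fixture speciation (99.68/0.32 and 0.10/99.77/0.13) |
| pKa reference constant | 14.0 | — | additive constant of the hydroxide-exchange pKa scheme (via pK_w); configurable because other proton-exchange references shift it |
| water viscosity | 8.91×10⁻⁴ | Pa·s | 298 K literature value, used by Stokes–Einstein |
| pentyl ethanoate viscosity | 8.62×10⁻⁴ | Pa·s | literature value for the lipid mimic |
| default hydrodynamic radius | 2.0 | Å | per diffusing partner when a medium supplies no diffusion-limit override; small-molecule scale |
| Marcus sign convention | `plus` | — | λ ≈ ΔE_SET + ΔG⁰_SET; the minus convention is offered because both circulate, and a non-positive λ raises an error naming the alternative |

Transcribed media carry explicit per-radical diffusion-limit overrides
(e.g. 2.60×10⁹ / 2.30×10⁹ M⁻¹ s⁻¹ for HO˙) because the radii behind the
published diffusion constants are not printed; the Smoluchowski estimate is
the fallback, not a replacement for them.

## Numerical choices

**Eckart tunneling.**  The transmission probability of the asymmetric
Eckart barrier is evaluated in the standard dimensionless form
α_i = 2πV_i/(hcω) with P = [cosh(a+b) − cosh(a−b)] / [cosh(a+b) + cosh(d)],
d² = 4(α₁α₂ − π²/4); when α₁α₂ < π²/4 the cosh(d) term becomes
cos(2√(π²/4 − α₁α₂)).  Everything is computed in log space
(log-sinh/log-cosh plus `logaddexp`), since thick barriers reach
α of several hundred and naive cosh overflows — clipping instead of logs
silently breaks the classical limit.  The thermal average integrates from
the product asymptote max(0, V₁ − V₂) to V₁ + 40 k_B T (Boltzmann weight
~4×10⁻¹⁸ of the maximum at the cut) with adaptive quadrature at relative
tolerance 10⁻⁸ and a breakpoint at E = V₁; non-convergence raises with the
full parameter set in the message.  κ → 1 as ω → 0 (verified to 10⁻³ at
1 cm⁻¹) and κ decreases with temperature.

**Printed vs recomputed rates.**  Transcribed channels can carry both the
published apparent rate (`fixed_rate`) and the parameters behind it.  The
`printed` policy (default) prefers the fixed rate, so table arithmetic
(weights, branching, sums) is reproduced exactly; `recompute` rebuilds the
rate from ΔG‡/κ or Marcus inputs, which reproduces the published values to
within the 1-decimal rounding of the printed barriers (typically 1–6%).
Published tables round barriers to 0.1 kcal/mol, and 0.05 kcal/mol in an
exponential is ±9% at 298 K — comparisons against printed rates must budget
for that.

**Ingestion of κ = 0.0.**  A transmission coefficient printed as "0.0" is a
value that rounds to zero at one decimal, not a forbidden reaction (the
same row prints a nonzero rate).  The reader maps it to "absent" (κ = 1)
and logs a warning; the transcribed fixed rate keeps table reproduction
exact.  Recomputing such a channel from its barrier alone overestimates the
rate (the implied κ is ~0.02), which is why those rows keep their printed
rates.

**Back-solved fixture inputs.**  Three kinds of inputs the published tables
imply but do not print are back-solved once and recorded in the fixtures
with comments: (i) SET reaction free energies from inverting the Marcus
parabola at the printed (λ, ΔG‡), taking the normal-region root;
(ii) per-pair aqueous diffusion limits from the Collins–Kimball relation
k_D = 1/(1/k_app − 1/k) applied to printed rate pairs (all fall in
3.8–4.5×10⁹ M⁻¹ s⁻¹); (iii) two radical-addition rates from dividing the
printed weighted rate by the printed mole fraction.

**Degenerate inputs and tie-breaks.**  Collins–Kimball returns 0 when both
rates are 0 and the finite partner's value when one is infinite.
Exergonicity screening is strict (ΔG_r = 0 is dropped and logged); channels
with no recorded ΔG_r pass through unscreened.  Branching ratios on an
all-zero group raise rather than emit NaNs.  Weighted rates that are
exactly zero display as `~0`, which is what the published tables print for
rate-less rows; small-but-nonzero weighted rates are printed numerically
(the tables do the same down to 10⁻³ of the overall rate, so a relative
display cutoff would misrepresent them).  Speciation uses a base-10
log-softmax, so pH values far outside the pKa window cannot overflow.
Table percentages round half-up to two decimals.

## Synthetic data

The generator emulates the statistical shape of a multi-site phenolic
antioxidant profile: 1–6 donor sites with FHT barriers uniform in
2–25 kcal/mol (the published range spans ~0.1–6 kcal/mol for HO˙ and
16–22 kcal/mol for HOO˙), an aggregate RAF channel, SET channels for each
anion in water with λ uniform in 5–45 kcal/mol and ΔG⁰ drawn down to
−1.2 λ so the inverted region is occasionally exercised, up to three pKa
values in 3–12 with a 0.5-unit minimum spacing, and water (pH 7.4) plus a
lipid ester as media.  Tunneling inputs come either as sampled Eckart
parameters (frequencies 800–3200 cm⁻¹) or as plain coefficients, toggled by
`kappa_mode`, so both ingestion paths are tested.  Generation is
deterministic per seed (`numpy.random.default_rng`).

What the generator does **not** emulate: correlations between barrier and
reaction energy (no Evans–Polanyi structure), realistic frequency–barrier
coupling, medium-dependent barriers for the same site, or molecular
structure of any kind.  Passing the synthetic closure tests therefore
demonstrates schema validity, numerical robustness and invariant
preservation over a wide parameter space — not chemical accuracy for any
real compound; that is what the transcribed fixtures are for.

## Test problem sizes

The suite runs the pipeline closure over 125 seeds per tunneling mode,
checks the Eckart evaluator against a dense-trapezoid oracle (200 001
points) on a 24-point grid spanning barriers 1–25 kcal/mol, frequencies
300–3500 cm⁻¹ and 250–350 K at 0.5% tolerance, and exercises the
Collins–Kimball bound on 10⁶ random rate pairs; hypothesis-based property
tests run derandomized at 60 examples each.  The whole suite completes in
well under a minute.

## Known limitations

- The published table for the carboxylated compound + HOO˙ in water is
  internally inconsistent (its SET row prints k_f = 1.87×10⁶ while
  f × k_app = 1.56×10⁶); the pipeline reports the self-consistent value
  and the fixture documents the discrepancy.
- Chelation "constants" are reported dimensionless (K = exp(−ΔG/RT));
  the source table attaches M⁻¹ s⁻¹ units to them, which is dimensionally
  an equilibrium-vs-rate mismatch the package does not reproduce.
- Symmetry numbers default to 1 with equivalent sites enumerated as
  separate channels (the convention the transcribed tables follow, where
  the two phenolic OH sites appear as identical rows).
- Fe(III) chelation is accepted as input but ships without a reference
  fixture; no published numbers exist for it.
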