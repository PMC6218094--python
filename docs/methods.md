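# Methods

## Scope and model

`redoxqc` computes biochemical standard transformed reduction potentials
E'^m(pH 7, I = 0.25 M, 1 mM reactant standard state) for two-electron redox
couples, starting from per-conformer electronic single-point energies that an
electronic-structure code has already produced.  Running quantum chemistry is
out of scope: the package's contribution is everything downstream — the
thermodynamic transform chain, the per-category calibration, the fingerprint
alternative predictor, the cross-method outlier rule, the pair enumeration
and the carrier analysis.

The chain, per couple (oxidized form `ox`, reduced form `red`):

1. **Boltzmann conformer averaging.**  Each compound's conformer energies
   E_i (Hartree) are averaged with weights ∝ exp(−(E_i − E_min)/kT) at
   T = 298.15 K, computed via log-sum-exp.  The averaging temperature is not
   physically pinned down by the input data and is configurable; 298.15 K is
   the default.  Weights come from the single-point energies themselves
   (not a separate optimisation-stage energy, which the data model does not
   carry).
2. **SHE reference.**  ΔE_electronic = ⟨E_red⟩ − ⟨E_ox⟩ − E_H2, with the H2
   energy from the same model-chemistry tag, converted at
   1 Ha = 2625.50 kJ/mol.  Then E°(MS, pH 0) = −ΔE_electronic/(nF) with
   n = 2 throughout.  The couple is balanced as `ox + H2 → red` (plus
   NH3/H2O for the carbonyl→amine category).  Electronic energies stand in
   for reaction Gibbs energies; the neglected rovibrational terms are
   absorbed by the linear calibration.
3. **Speciation and Legendre transform.**  Each compound's pH-0 major
   species (the most protonated form, the one the electronic energies
   describe) anchors a deprotonation ladder built from its pKa list; the
   j-th deprotonation adds RT·ln10·pKa_j to the relative standard energy
   and lowers charge and hydrogen count by one.  Only pKa values in
   [0, 14] generate species — values outside that window cannot move a
   pH-7 pseudoisomer sum materially.  Each species energy gets
   N_H·RT·ln10·pH plus the extended Debye-Hückel correction
   −α(z² − N_H)√I/(1 + B√I) with Alberty's 298.15 K parameters
   α = 2.91482 kJ·mol⁻¹·M^(−1/2), B = 1.6 M^(−1/2); α's temperature
   dependence is not modelled because the pipeline operates at 298.15 K.
   Species are aggregated into one pseudoisomer energy by
   −RT·ln Σ exp(−ΔG'_j/RT).
4. **Transformed potential.**  Only the transform corrections are added to
   the electronic-energy-derived potential:
   E'° = E° − [(G'_red − G°_red,MS) − (G'_ox − G°_ox,MS)]/(nF).
   The standard hydrogen electrode is defined at unit proton activity and
   unit H2 fugacity, so the H2 reference carries no transform correction;
   working directly on potentials in this correction-difference form is
   algebraically equivalent to transforming Gibbs energies and then
   converting.  For a hydrogen-balanced couple with no pKa in range this
   reduces to the classical slope dE'°/dpH = −(ΔN_H/n)·RT·ln10/F
   (−59.16 mV per pH unit for 2 H⁺/2 e⁻).
5. **1 mM standard state.**  E'^m = E'° − (RT/(nF))·Σν_i·ln(c°/1 M) over
   concentration-adjusted reactants (products positive); water, H2 and
   protons are exempt.  One-substrate/one-product categories are unchanged;
   the ammonia substrate of carbonyl→amine reductions lowers E'^m by
   RT·ln(10³)/(nF) = 88.73 mV, which is what brings that category onto the
   carbonyl→hydroxycarbon distribution at the millimolar state.  The sign
   convention is pinned by a dedicated coincidence test.
6. **Activation.**  Activated (thioester/phosphoanhydride) acid couples are
   modelled as a flat, configurable +250 mV shift of the unactivated
   potential — the rounded display convention for the ~50 kJ/mol hydrolysis
   energy over two electrons (unrounded: 259.1 mV) — not as a per-compound
   thermodynamic cycle.

## Calibration, fingerprints, outliers

Each oxidoreductase category (G1 acid→carbonyl, G2 carbonyl→hydroxycarbon,
G3 carbonyl→amine, G4 hydroxycarbon→hydrocarbon) gets a two-parameter OLS
calibration of experimental E'^m on raw predictions, paired by reaction id.
Activated-acid records share the G1 model: there are too few of them to fit
separately.  Metrics (MAE, Pearson r, R² = 1 − SS_res/SS_tot, which may be
negative) are in-sample; no cross-validation is applied to the headline
metrics because the calibration is deliberately minimal.

The fingerprint predictor encodes each compound's pH-0 major-species SMILES
as the 166 public MACCS keys (via RDKit), concatenates substrate then
product into a 332-bit reaction fingerprint, and fits one L1-regularised
(Lasso) linear model per category.  The concatenated design deliberately
keeps substrate and product halves separate rather than differencing them.
λ defaults to internal k-fold cross-validation over a config-exposed grid;
λ = 0 falls back to ordinary least squares.  Circular fingerprints are
deliberately not offered: at these training-set sizes they overfit.

Outlier detection: per-method prediction errors are z-scored with the
sample standard deviation (ddof = 1; the population estimator would differ
only by a common factor, but the choice is documented because it changes
individual z values).  A record is flagged only when |z| > 2 for **both**
methods.  The absolute value is used rather than a one-sided rule: a
consistently signed deviation is the observed failure mode, but a
symmetric rule cannot miss the mirrored case and subsumes the one-sided
reading.

## Enumeration

Candidate pairs are mined by matching product-minus-substrate functional-
group difference vectors against per-category signatures over a declared
basis (`carboxylic_acid`, `carbonyl`, `hydroxycarbon`, `amine`).  Group
vectors are *inputs*; no decomposition engine is implemented, which
sidesteps the decomposition failures that plague group-contribution
pipelines.  Both compounds must have fewer than 7 carbons.  Pairs are
stored as reductions, output deterministically sorted, and re-checked by an
independent verifier.  Two name-based filters follow: a stereo-token filter
(R/S, L/D parsed from names; conflicting tokens drop the pair, absent
tokens pass) and a sugar-family filter (a configurable table of name roots
per carbon skeleton; cross-family pairs such as an L-pentonate reduced to a
different L-pentose are dropped and logged).  The shipped family table is a
small default covering the common pentoses/hexoses and is user-extensible;
it approximates, with explicit logged rules, curation that was originally
partly manual.

## Carrier analysis

NAD(P)'s physiological range is −380 to −250 mV (standard potential
~−330 mV at pH 7, I 0.25 M, widened by the in-vivo span of its redox
ratio).  Metabolite concentrations spanning 10⁴-fold (1 μM–10 mM) offset a
couple's effective potential by up to RT·ln(10⁴)/(2F) = 118.3 mV, so the
reversibility window is [−500, −130] mV after the nearest-5-mV display
rounding.  Couples inside the (closed) window classify `reversible`; below
it the carrier can only oxidize the couple's reduced form
(`oxidation_only`); above it, only reduce (`reduction_only`).  Window
boundaries classify as reversible by convention.  Subgroup contrasts use
Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
freedom; raw p-values are reported by default (matching the field's
convention for these comparisons), with Benjamini–Hochberg available
behind a flag.  Display rounding to the nearest 5 mV is applied only at
the reporting layer.

## Synthetic data

The fixture generator (`redoxqc.fixtures`) emulates the study's data
shapes with planted ground truth:

* conformer ensembles (3–10 conformers, gaps uniform on 0–8 kJ/mol) shifted
  so their exact Boltzmann mean — computed by direct summation, independent
  of the pipeline's log-sum-exp path — is prescribed; pair target
  potentials are drawn N(category mean, 50 mV) around the literature
  category means (−550/−225/−225/−15 mV) and realised exactly through the
  compound-energy assignment;
* calibration sets sized like the experimental compilation (G1 8, G2 59,
  G3 23, G4 15) from the affine law exp = 0.8·raw + 30 mV + N(0, 10 mV);
* a cross-method error set (n = 59) whose background errors are uniform on
  ±σ — bounded, so no background point can reach |z| = 2 — with one planted
  4σ joint outlier, making recovery exact rather than probabilistic;
* a two-subgroup set (n = 40 each, σ = 20 mV) with a planted 30 mV offset;
* a toy compound table with hand-assigned group vectors containing planted
  matches for all four signatures, a 7-carbon exclusion case, an R-vs-S
  conflict and the classic wrong cross-family sugar pair.

What passing on these fixtures does **not** show: accuracy of real
electronic-structure energies or pKa estimates, the empirical error
distribution of real experimental compilations (which is heavier-tailed
than the planted Gaussians/uniforms), or coverage of a real metabolite
database's group-vector diversity.  The fixtures validate the machinery —
transforms, fits, rules — not the physics upstream of it.

## Numerical choices and degenerate inputs

* Log-sum-exp (minimum-shifted) everywhere a Boltzmann sum appears; no
  overflow for arbitrarily separated energies.
* Potentials round-trip volts↔kJ/mol to < 1e-12 relative error.
* Ladder validation: successive species must step charge and hydrogen
  count down by exactly 1; more in-window pKa values than hydrogens is an
  error.  Near-ties in the major-species diagnostic (within 1e-9 kJ/mol)
  resolve toward the more protonated species.
* Duplicate conformer energies are kept; they do not change the weighted
  mean.
* Zero-spread error vectors reject z-scoring; constant experimental
  vectors yield NaN (not an exception) for Pearson r and R².
* CSV floats are written at 17 significant digits and read with pandas'
  round-trip parser, so all tables round-trip bit-exactly.

## Problem sizes

The test suite and the acceptance script run entirely on the synthetic
study: 18 compounds, 10 planted reactions, 105 calibration records, a
59-record outlier set and an 80-record subgroup set; fingerprint-regression
checks use up to 300 synthetic training rows over the 332-bit design.
These sizes exercise every code path while keeping any single check under a
second.

## Known limitations

* Half-reactions only; no general Gibbs formation-energy bookkeeping.
* No temperature extrapolation (constants parameterised at 298.15 K) and
  no activity model beyond extended Debye-Hückel.
* pKa values, group vectors and electronic energies are trusted inputs;
  the package neither predicts pKa nor decomposes structures into groups.
* The activation correction is a distribution-level constant, not
  compound-specific energetics.
* Natural/non-natural flagging is a join against a user-provided known-
  reaction table, not a live database query.
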