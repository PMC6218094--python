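# redoxqc

Calibrated quantum-chemistry prediction of biochemical redox potentials.

Most of cellular metabolism runs on two-electron redox chemistry, yet only
on the order of a hundred reduction potentials can be inferred from
experiment, under inconsistent conditions.  `redoxqc` implements the
post-electronic-structure half of a quantum-chemistry pipeline for
predicting them at scale: given per-conformer electronic energies (from any
DFT/wave-function code), pKa ladders and compound metadata, it produces
biochemical standard transformed potentials and the downstream analyses
that make them useful — calibration against experiment, error screening,
reaction enumeration and electron-carrier compatibility.  It is written for
computational biochemists and metabolic engineers who have electronic
energies in hand and want defensible E'^m values and comparisons out.

## The model

For a couple balanced as `ox + H2 → red` (n = 2 electrons, standard
hydrogen electrode reference):

    E°(MS, pH 0) = −ΔE_electronic / nF,
    ΔE_electronic = ⟨E_red⟩ − ⟨E_ox⟩ − E_H2

with ⟨·⟩ the Boltzmann average over conformers.  Protonation-state ladders
built from pKa values give each compound a pseudoisomer (ensemble) energy

    G' = −RT ln Σ_j exp(−ΔG'_j / RT),
    ΔG'_j = ΔG°_j + N_H·RT·ln10·pH − α(z² − N_H)√I/(1 + B√I)

(Alberty-Legendre transform plus extended Debye-Hückel), from which

    E'° = E°(MS, pH 0) − [ΔG'_corr(red) − ΔG'_corr(ox)] / nF

and a concentration re-standardisation to the 1 mM ("m") state gives E'^m.
Raw per-category predictions are calibrated against experimental values by
two-parameter linear regression (E'^m_cal = α·E'^m_raw + β).  An
independent MACCS-key reaction-fingerprint Lasso regressor provides a
second prediction route; records that both methods miss by |z| > 2 are
flagged as probable experimental errors.  Candidate redox pairs are
enumerated by functional-group difference signatures with size, chirality
and sugar-name filters, and every potential is classified against a
carrier's reversibility window (NAD(P): [−380, −250] mV widened by
±RT·ln(10⁴)/2F ≈ ±120 mV).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

A carbonyl→hydroxycarbon reduction (pyruvate → lactate style) from
conformer energies:

```python
from redoxqc import qc, thermo
from redoxqc.enumeration import RedoxPair
from redoxqc.qc import ConformerEnergySet, ReferenceEnergies
from redoxqc.speciation import Compound

pair = RedoxPair("pyr", "lac", "G2")
ensembles = {
    "pyr": ConformerEnergySet("pyr", (-342.1501, -342.1487, -342.1482), "b2plyp"),
    "lac": ConformerEnergySet("lac", (-343.3334, -343.3321), "b2plyp"),
}
refs = ReferenceEnergies({"b2plyp": -1.1675})
compounds = {
    "pyr": Compound("pyr", "Pyruvate", "CC(=O)C(=O)O", 0, 4, 3, (2.5,), {}),
    "lac": Compound("lac", "(S)-Lactate", "C[C@H](O)C(=O)O", 0, 6, 3, (3.9,), {}),
}
est = qc.estimate_pair_potential(pair, compounds, ensembles, refs)
print(f"E°(MS, pH 0)  = {est.e_standard_ph0*1000:+.1f} mV")
print(f"E'°(pH 7)     = {est.e_prime_standard*1000:+.1f} mV")
print(f"E'^m (1 mM)   = {est.e_prime_m*1000:+.1f} mV")
ratio = thermo.equilibrium_ratio(-0.330, est.e_prime_m)
print(f"[lactate]/[pyruvate] at NAD(P) equilibrium ~ {ratio:,.0f}")
```

prints

```
E°(MS, pH 0)  = +217.1 mV
E'°(pH 7)     = -246.8 mV
E'^m (1 mM)   = -246.8 mV
[lactate]/[pyruvate] at NAD(P) equilibrium ~ 652
```

The chemical-species potential at pH 0 (+217 mV) drops by the two-proton
−59.16 mV/pH slope, the ionic-strength correction and the pKa ladder terms
to −247 mV at pH 7; for this one-substrate/one-product category the 1 mM
re-standardisation cancels, so E'^m = E'°.  A carrier poised at −330 mV
then holds the carbonyl ~650-fold below its hydroxycarbon at equilibrium —
the thermodynamic logic by which NAD(P) keeps reactive carbonyls scarce.

The same chain is available from the shell:

```sh
redoxqc fixtures --seed 1 --out scratch/fx        # synthetic study tables
redoxqc predict --compounds scratch/fx/compounds.csv \
    --energies scratch/fx/energies.csv \
    --h2-reference scratch/fx/h2_reference.csv \
    --reactions scratch/fx/reactions.csv --out scratch/estimates.csv
redoxqc calibrate --predictions scratch/estimates.csv \
    --experimental scratch/fx/experimental.csv --out scratch/calibrated.csv
```

plus `fingerprint-fit`, `outliers`, `enumerate` and `analyze`.

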