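"""Closed-form biochemical redox thermodynamics.

This module holds everything needed to move a standard reduction potential of
the chemically defined major species at pH 0, ``E°(MS, pH 0)``, to the
biochemical standard transformed potential ``E'^m`` at specified pH, ionic
strength and a 1 mM reactant standard state:

* extended Debye-Hückel activity corrections per protonation species,
* the Legendre transform that makes pH an independent variable,
* pseudoisomer (protonation-ensemble) aggregation by log-sum-exp,
* the concentration re-standardisation from the 1 M ("o") to the 1 mM ("m")
  state, and
* small closed-form helpers used in carrier-compatibility analysis
  (equilibrium ratios, reversibility windows, Keq-to-potential shifts).

Potentials are in volts, energies in kJ/mol, temperatures in kelvin.
All half-reactions are treated as two-electron reductions referenced to the
standard hydrogen electrode, balanced as ``ox + H2 -> red`` (plus NH3/H2O
co-reactants where the category requires them).  Because the SHE reference is
defined at unit proton activity (pH 0) and unit H2 fugacity, the H2 side of
the balance carries no transform correction; the pH dependence of a couple
enters through the hydrogen-count difference of the oxidized and reduced
pseudoisomer groups.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "AqueousConditions",
    "ProtonationSpecies",
    "PotentialEstimate",
    "H2_SPECIES",
    "debye_huckel_term",
    "legendre_transform_species",
    "pseudoisomer_energy",
    "reaction_transformed_potential",
    "to_millimolar_standard",
    "category_stoichiometry",
    "activation_correction",
    "activation_shift_from_hydrolysis",
    "equilibrium_ratio",
    "reversibility_window",
    "keq_shift_to_potential",
    "volts_to_kj_per_mol",
    "kj_per_mol_to_volts",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants used throughout the pipeline.

    ``debye_huckel_alpha`` is Alberty's 298.15 K value in
    kJ mol^-1 (mol/L)^-1/2 and ``debye_huckel_b`` the matching ion-size
    parameter in (mol/L)^-1/2; their temperature dependence is not modelled
    (the pipeline operates at 298.15 K).
    """

    R: float = 8.314          # J mol^-1 K^-1
    F: float = 96485.0        # C mol^-1
    hartree_to_kj_per_mol: float = 2625.50
    debye_huckel_alpha: float = 2.91482
    debye_huckel_b: float = 1.6

    def __post_init__(self) -> None:
        for name in (
            "R",
            "F",
            "hartree_to_kj_per_mol",
            "debye_huckel_alpha",
            "debye_huckel_b",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def rt_kj(self, temperature: float) -> float:
        """R*T in kJ/mol."""
        return self.R * temperature / 1000.0


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class AqueousConditions:
    """Aqueous reference conditions for transformed quantities.

    ``standard_concentration`` is the reactant standard state in mol/L:
    0.001 for the physiological "m" convention, 1.0 for the classical "o"
    convention.
    """

    ph: float = 7.0
    ionic_strength: float = 0.25
    temperature: float = 298.15
    standard_concentration: float = 0.001

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ValueError(
                f"ionic_strength must be non-negative, got {self.ionic_strength}"
            )
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not self.standard_concentration > 0:
            raise ValueError(
                "standard_concentration must be positive, got "
                f"{self.standard_concentration}"
            )


@dataclass(frozen=True)
class ProtonationSpecies:
    """One protonation state of a compound.

    ``dg0`` is the chemical standard Gibbs energy relative to the major
    species at pH 0 (which therefore has ``dg0 == 0``); ``charge`` and
    ``n_hydrogens`` drop by exactly 1 per deprotonation step.
    """

    charge: int
    n_hydrogens: int
    dg0: float = 0.0  # kJ/mol, relative to the pH-0 major species

    def __post_init__(self) -> None:
        if self.n_hydrogens < 0:
            raise ValueError("n_hydrogens must be non-negative")
        if not math.isfinite(self.dg0):
            raise ValueError("dg0 must be finite")


#: Molecular hydrogen as the electron/proton source of every half-reaction.
#: At the SHE reference state its transform correction vanishes identically.
H2_SPECIES = ProtonationSpecies(charge=0, n_hydrogens=2, dg0=0.0)


@dataclass(frozen=True)
class PotentialEstimate:
    """The chain E°(MS, pH 0) -> E'° (pH, I) -> E'^m (1 mM) for one couple."""

    pair_id: str
    e_standard_ph0: float
    e_prime_standard: float
    e_prime_m: float | None
    method: str  # qc_raw | qc_calibrated | fingerprint | external
    conditions: AqueousConditions = field(default_factory=AqueousConditions)

    def __post_init__(self) -> None:
        for name in ("e_standard_ph0", "e_prime_standard"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.e_prime_m is not None:
            if not math.isfinite(self.e_prime_m):
                raise ValueError("e_prime_m must be finite")
            if self.conditions.standard_concentration != 0.001:
                raise ValueError(
                    "e_prime_m is defined only at the 1 mM standard state"
                )


def debye_huckel_term(
    charge: int,
    n_hydrogens: int,
    ionic_strength: float,
    temperature: float = 298.15,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Extended Debye-Hückel energy correction for one species, kJ/mol.

    Returns ``-alpha * (z^2 - N_H) * sqrt(I) / (1 + B*sqrt(I))``; zero at
    zero ionic strength and for species with z^2 == N_H.  Even in the sign
    of the charge.
    """
    if ionic_strength < 0:
        raise ValueError(
            f"ionic_strength must be non-negative, got {ionic_strength}"
        )
    del temperature  # alpha is parameterised at 298.15 K
    sqrt_i = math.sqrt(ionic_strength)
    return (
        -constants.debye_huckel_alpha
        * (charge * charge - n_hydrogens)
        * sqrt_i
        / (1.0 + constants.debye_huckel_b * sqrt_i)
    )


def legendre_transform_species(
    species: ProtonationSpecies,
    conditions: AqueousConditions,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Transformed standard Gibbs energy of one species, kJ/mol.

    ΔG' = ΔG° + N_H·RT·ln10·pH + Debye-Hückel(z, N_H, I).  At pH 0, I 0 this
    is the identity on ΔG°.
    """
    rt = constants.rt_kj(conditions.temperature)
    return (
        species.dg0
        + species.n_hydrogens * rt * LN10 * conditions.ph
        + debye_huckel_term(
            species.charge,
            species.n_hydrogens,
            conditions.ionic_strength,
            conditions.temperature,
            constants,
        )
    )


def pseudoisomer_energy(
    transformed_energies: Sequence[float],
    temperature: float = 298.15,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Aggregate species transformed energies into one pseudoisomer energy.

    Returns ``-RT ln sum_j exp(-G'_j / RT)`` computed with a log-sum-exp
    shift, so widely separated energies do not overflow.  The result is at
    most the minimum input energy, and adding a species can only lower it.
    """
    if len(transformed_energies) == 0:
        raise ValueError("pseudoisomer_energy requires at least one species")
    rt = constants.rt_kj(temperature)
    g = np.asarray(transformed_energies, dtype=float)
    return float(-rt * logsumexp(-g / rt))


def _validate_ladder(ladder: Sequence[ProtonationSpecies], label: str) -> None:
    if len(ladder) == 0:
        raise ValueError(f"{label}: species ladder is empty")
    if ladder[0].dg0 != 0.0:
        raise ValueError(f"{label}: major species must have dg0 == 0")
    for j in range(1, len(ladder)):
        prev, cur = ladder[j - 1], ladder[j]
        if cur.charge != prev.charge - 1 or cur.n_hydrogens != prev.n_hydrogens - 1:
            raise ValueError(
                f"{label}: species {j} does not step charge and hydrogen "
                "count down by exactly 1"
            )


def reaction_transformed_potential(
    e_standard_ph0: float,
    oxidized_ladder: Sequence[ProtonationSpecies],
    reduced_ladder: Sequence[ProtonationSpecies],
    conditions: AqueousConditions | None = None,
    n_electrons: int = 2,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Standard transformed potential E'° (V) of a reduction half-reaction.

    The couple is balanced as ``ox + H2 -> red`` against the standard
    hydrogen electrode.  Only the transform corrections are added to the
    electronic-energy-derived ``E°(MS, pH 0)``:

        E'° = E° - [(G'_red - G°_red,MS) - (G'_ox - G°_ox,MS)] / (nF)

    where each G' is the pseudoisomer aggregate of the Legendre-transformed
    species ladder and each G°_MS is zero by construction (ladder energies
    are relative to the pH-0 major species).  The H2 reference is at the SHE
    standard state and contributes no correction; for a hydrogen-balanced
    couple with no pKa in range this yields the classical
    ``-(ΔN_H/n)·RT·ln10/F`` slope per pH unit (−59.16 mV/pH for 2 H⁺ / 2 e⁻
    at 298.15 K).
    """
    if conditions is None:
        conditions = AqueousConditions()
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    _validate_ladder(oxidized_ladder, "oxidized")
    _validate_ladder(reduced_ladder, "reduced")

    def correction(ladder: Sequence[ProtonationSpecies]) -> float:
        transformed = [
            legendre_transform_species(s, conditions, constants) for s in ladder
        ]
        return pseudoisomer_energy(
            transformed, conditions.temperature, constants
        )

    delta_kj = correction(reduced_ladder) - correction(oxidized_ladder)
    return e_standard_ph0 - delta_kj * 1000.0 / (n_electrons * constants.F)


#: Reactants excluded from the concentration re-standardisation: water (unit
#: activity), H2 (gas reference) and protons (absorbed by the transform).
_ADJUSTMENT_EXEMPT = {"h2", "h2o", "water", "h+", "proton", "h"}

#: Net stoichiometry of each oxidoreductase category, written as a reduction.
#: Keys are reactant roles; values are signed coefficients (products > 0).
_CATEGORY_STOICHIOMETRY: Mapping[str, Mapping[str, float]] = {
    # acid + H2 -> carbonyl + H2O
    "G1": {"substrate": -1, "h2": -1, "product": +1, "h2o": +1},
    "G1-activated": {"substrate": -1, "h2": -1, "product": +1, "h2o": +1},
    # carbonyl + H2 -> hydroxycarbon
    "G2": {"substrate": -1, "h2": -1, "product": +1},
    # carbonyl + NH3 + H2 -> amine + H2O
    "G3": {"substrate": -1, "nh3": -1, "h2": -1, "product": +1, "h2o": +1},
    # hydroxycarbon + H2 -> hydrocarbon + H2O
    "G4": {"substrate": -1, "h2": -1, "product": +1, "h2o": +1},
}


def category_stoichiometry(category: str) -> Mapping[str, float]:
    """Signed reactant coefficients of an oxidoreductase category."""
    try:
        return dict(_CATEGORY_STOICHIOMETRY[category])
    except KeyError:
        raise ValueError(f"unknown redox category: {category!r}") from None


def to_millimolar_standard(
    e_prime_standard: float,
    stoichiometry: Mapping[str, float],
    conditions: AqueousConditions | None = None,
    n_electrons: int = 2,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Re-standardise E'° to the conditions' concentration standard state.

    ``E'^m = E'° - (RT/(nF)) * sum_i nu_i * ln(c°/1 M)`` over the
    concentration-adjusted reactants (products positive, substrates
    negative); water, H2 and protons are exempt.  For 1:1 couples (G1, G2,
    G4) the adjustment cancels and ``E'^m == E'°``; the ammonia substrate of
    G3 lowers the potential by RT·ln(10³)/(nF) = 88.7 mV at the 1 mM state.
    """
    if conditions is None:
        conditions = AqueousConditions()
    net_nu = sum(
        coeff
        for name, coeff in stoichiometry.items()
        if name.lower() not in _ADJUSTMENT_EXEMPT
    )
    rt_j = constants.R * conditions.temperature
    log_c = math.log(conditions.standard_concentration / 1.0)
    return e_prime_standard - (rt_j / (n_electrons * constants.F)) * net_nu * log_c


def activation_correction(e_prime_m: float, offset: float = 0.250) -> float:
    """Potential of the activated (thioester/phosphoanhydride) acid couple.

    Activation of a carboxylic acid releases ~50 kJ/mol on hydrolysis, which
    raises the reduction potential of the couple by ~offset volts; the
    default is the conventional flat +250 mV shift.
    """
    return e_prime_m + offset


def activation_shift_from_hydrolysis(
    hydrolysis_energy_kj: float = 50.0,
    n_electrons: int = 2,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Unrounded activation shift (V) implied by a hydrolysis energy.

    50 kJ/mol over two electrons gives 259.1 mV, the physical basis of the
    rounded +250 mV default of :func:`activation_correction`.
    """
    return hydrolysis_energy_kj * 1000.0 / (n_electrons * constants.F)


def equilibrium_ratio(
    e_carrier: float,
    e_prime_m: float,
    n_electrons: int = 2,
    temperature: float = 298.15,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Equilibrium [reduced]/[oxidized] ratio imposed by a carrier.

    ``exp(-(E_carrier - E'^m) * nF / RT)``: a carrier poised below the
    couple's potential pushes the couple toward its reduced form.
    """
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    rt_j = constants.R * temperature
    return math.exp(
        -(e_carrier - e_prime_m) * n_electrons * constants.F / rt_j
    )


def reversibility_window(
    e_low: float,
    e_high: float,
    concentration_span: float,
    n_electrons: int = 2,
    temperature: float = 298.15,
    round_to_mv: float | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[float, float]:
    """Potential window a carrier can drive reversibly.

    Metabolite concentrations varying over ``concentration_span`` offset a
    couple's effective potential by up to ``w = RT ln(span) / (nF)`` in
    either direction, so the carrier's physiological range [e_low, e_high]
    widens to ``(e_low - w, e_high + w)``.  ``round_to_mv`` optionally rounds
    the half-width to the nearest multiple (display convention, e.g. 5 mV).
    """
    if e_low > e_high:
        raise ValueError("e_low must not exceed e_high")
    if concentration_span < 1:
        raise ValueError(
            f"concentration_span must be >= 1, got {concentration_span}"
        )
    w = keq_shift_to_potential(
        concentration_span, n_electrons, temperature, constants
    )
    if round_to_mv is not None:
        w = round(w * 1000.0 / round_to_mv) * round_to_mv / 1000.0
    return (e_low - w, e_high + w)


def keq_shift_to_potential(
    k_eq: float,
    n_electrons: int = 2,
    temperature: float = 298.15,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Potential shift ΔE = RT·ln(K)/(nF) equivalent to an equilibrium constant."""
    if k_eq <= 0:
        raise ValueError(f"k_eq must be positive, got {k_eq}")
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    return constants.R * temperature * math.log(k_eq) / (n_electrons * constants.F)


def volts_to_kj_per_mol(
    potential: float, n_electrons: int = 2, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Reduction potential (V) to reaction Gibbs energy (kJ/mol), ΔG = -nFE."""
    return -n_electrons * constants.F * potential / 1000.0


def kj_per_mol_to_volts(
    energy_kj: float, n_electrons: int = 2, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Reaction Gibbs energy (kJ/mol) to reduction potential (V), E = -ΔG/(nF)."""
    return -energy_kj * 1000.0 / (n_electrons * constants.F)
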