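"""From conformer electronic energies to SHE-referenced standard potentials.

Electronic single-point energies of pre-optimized conformers are the input;
they already contain solvent and dispersion contributions.  Conformers are
Boltzmann-averaged, the molecular-hydrogen energy (same model chemistry) is
subtracted to reference the couple to the standard hydrogen electrode, and
the reaction electronic-energy difference is mapped to a potential through
ΔE_electronic ≈ -nF·E°(MS, pH 0).  Vibrational/rotational thermochemistry is
deliberately absent — the downstream per-category linear calibration absorbs
it.

Units: Hartree at the file boundary, kJ/mol internally, volts for
potentials (1 Ha = 2625.50 kJ/mol).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .enumeration import RedoxPair
from .speciation import Compound, build_species_ladder
from .thermo import (
    CONSTANTS,
    AqueousConditions,
    PhysicalConstants,
    PotentialEstimate,
    category_stoichiometry,
    reaction_transformed_potential,
    to_millimolar_standard,
)

__all__ = [
    "ConformerEnergySet",
    "ReferenceEnergies",
    "boltzmann_average",
    "reaction_delta_electronic",
    "electronic_to_standard_potential",
    "estimate_pair_potential",
    "estimate_potentials",
]


@dataclass(frozen=True)
class ConformerEnergySet:
    """Electronic energies (Hartree) of one compound's conformer ensemble."""

    compound_id: str
    energies: tuple[float, ...]
    model_chemistry: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.energies) == 0:
            raise ValueError(f"{self.compound_id}: empty conformer ensemble")
        if any(not math.isfinite(e) for e in self.energies):
            raise ValueError(f"{self.compound_id}: non-finite conformer energy")


@dataclass(frozen=True)
class ReferenceEnergies:
    """H2 electronic energy (Hartree) per model-chemistry tag."""

    h2_energy: Mapping[str, float] = field(default_factory=dict)

    def h2_for(self, model_chemistry: str) -> float:
        try:
            return self.h2_energy[model_chemistry]
        except KeyError:
            raise KeyError(
                f"no H2 reference energy for model chemistry {model_chemistry!r}"
            ) from None


def boltzmann_average(
    energies: Sequence[float],
    temperature: float = 298.15,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Boltzmann-weighted mean electronic energy (Hartree).

    Weights are exp(-(E_i - E_min)/kT) with the gap converted from Hartree
    to kJ/mol; the minimum shift keeps the weights finite for widely
    separated conformers.  The result lies in [min, max] of the inputs,
    tending to the minimum as T -> 0 and the arithmetic mean as T -> inf.
    """
    if len(energies) == 0:
        raise ValueError("boltzmann_average requires at least one energy")
    e = np.asarray(energies, dtype=float)
    rt = constants.rt_kj(temperature)
    gaps_kj = (e - e.min()) * constants.hartree_to_kj_per_mol
    log_w = -gaps_kj / rt
    log_z = logsumexp(log_w)
    weights = np.exp(log_w - log_z)
    return float(np.dot(weights, e))


def reaction_delta_electronic(
    pair: RedoxPair,
    ensembles: Mapping[str, ConformerEnergySet],
    references: ReferenceEnergies,
    temperature: float = 298.15,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """SHE-referenced reaction electronic-energy difference, kJ/mol.

    ΔE = <E_red> - <E_ox> - E_H2 over Boltzmann-averaged ensembles sharing
    one model-chemistry tag.
    """
    try:
        ox = ensembles[pair.substrate_id]
    except KeyError:
        raise KeyError(f"no conformer ensemble for {pair.substrate_id!r}") from None
    try:
        red = ensembles[pair.product_id]
    except KeyError:
        raise KeyError(f"no conformer ensemble for {pair.product_id!r}") from None
    if ox.model_chemistry != red.model_chemistry:
        raise ValueError(
            f"model chemistry mismatch for pair {pair.substrate_id} -> "
            f"{pair.product_id}: {ox.model_chemistry!r} vs {red.model_chemistry!r}"
        )
    e_h2 = references.h2_for(ox.model_chemistry)
    delta_hartree = (
        boltzmann_average(red.energies, temperature, constants)
        - boltzmann_average(ox.energies, temperature, constants)
        - e_h2
    )
    return delta_hartree * constants.hartree_to_kj_per_mol


def electronic_to_standard_potential(
    delta_electronic_kj: float,
    n_electrons: int = 2,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """E°(MS, pH 0) in volts from a reaction electronic energy in kJ/mol.

    E° = -ΔE_electronic/(nF): a more exergonic reduction gives a higher
    potential.
    """
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    return -delta_electronic_kj * 1000.0 / (n_electrons * constants.F)


def estimate_pair_potential(
    pair: RedoxPair,
    compounds: Mapping[str, Compound],
    ensembles: Mapping[str, ConformerEnergySet],
    references: ReferenceEnergies,
    conditions: AqueousConditions | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> PotentialEstimate:
    """Full chain E°(MS, pH 0) -> E'°(pH, I) -> E'^m for one redox pair."""
    if conditions is None:
        conditions = AqueousConditions()
    delta = reaction_delta_electronic(
        pair, ensembles, references, conditions.temperature, constants
    )
    e0 = electronic_to_standard_potential(delta, pair.n_electrons, constants)
    ox_ladder = build_species_ladder(
        compounds[pair.substrate_id], conditions.temperature, constants
    )
    red_ladder = build_species_ladder(
        compounds[pair.product_id], conditions.temperature, constants
    )
    e_prime = reaction_transformed_potential(
        e0, ox_ladder, red_ladder, conditions, pair.n_electrons, constants
    )
    e_prime_m = to_millimolar_standard(
        e_prime,
        category_stoichiometry(pair.category),
        conditions,
        pair.n_electrons,
        constants,
    )
    return PotentialEstimate(
        pair_id=f"{pair.substrate_id}__{pair.product_id}",
        e_standard_ph0=e0,
        e_prime_standard=e_prime,
        e_prime_m=e_prime_m if conditions.standard_concentration == 0.001 else None,
        method="qc_raw",
        conditions=conditions,
    )


def estimate_potentials(
    pairs: Iterable[RedoxPair],
    compounds: Mapping[str, Compound],
    ensembles: Mapping[str, ConformerEnergySet],
    references: ReferenceEnergies,
    conditions: AqueousConditions | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> list[PotentialEstimate]:
    """Vectorised convenience wrapper over :func:`estimate_pair_potential`."""
    return [
        estimate_pair_potential(
            pair, compounds, ensembles, references, conditions, constants
        )
        for pair in pairs
    ]
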