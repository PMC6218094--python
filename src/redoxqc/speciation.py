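"""Protonation-species ladders.

A biochemical reactant is an ensemble of protonation states.  Calculations
anchor on the major species at pH 0 (the most protonated form, the one the
electronic-structure energies describe) and build the ladder of successive
deprotonations from a supplied pKa list; pKa values are inputs, produced
upstream by a cheminformatic estimator.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .thermo import (
    CONSTANTS,
    LN10,
    AqueousConditions,
    PhysicalConstants,
    ProtonationSpecies,
    legendre_transform_species,
)

__all__ = [
    "Compound",
    "PKA_WINDOW",
    "build_species_ladder",
    "major_species_at_ph",
    "parse_stereo_tokens",
]

#: Deprotonations with pKa outside this window cannot shift a pH-7
#: pseudoisomer sum materially and are ignored when building ladders.
PKA_WINDOW = (0.0, 14.0)

_RS_PATTERN = re.compile(r"\(\s*(?:\d+)?([RS])(?:\s*,\s*(?:\d+)?[RS])*\s*\)")
_RS_TOKEN = re.compile(r"(?:\d+)?([RS])")
_LD_PATTERN = re.compile(r"(?:^|[\s(,-])([LD])-")


def parse_stereo_tokens(name: str) -> frozenset[str]:
    """Stereo descriptors (R/S, L/D) mentioned in a compound name."""
    tokens: set[str] = set()
    for match in _RS_PATTERN.finditer(name):
        tokens.update(_RS_TOKEN.findall(match.group(0)))
    tokens.update(_LD_PATTERN.findall(name))
    return frozenset(tokens)


@dataclass(frozen=True)
class Compound:
    """A compound anchored at its pH-0 major species.

    ``pka_values`` are listed in the order protons are removed from the major
    species; ``group_vector`` counts occurrences of each functional group in
    a shared named basis; ``charge``/``n_hydrogens`` describe the major
    species itself.
    """

    id: str
    name: str = ""
    smiles: str = ""
    charge: int = 0
    n_hydrogens: int = 0
    n_carbons: int = 0
    pka_values: tuple[float, ...] = ()
    group_vector: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise ValueError(f"{self.id}: n_carbons must be non-negative")
        if any(v < 0 for v in self.group_vector.values()):
            raise ValueError(f"{self.id}: group_vector counts must be >= 0")
        if any(not math.isfinite(p) for p in self.pka_values):
            raise ValueError(f"{self.id}: pKa values must be finite")

    @property
    def stereo_tokens(self) -> frozenset[str]:
        return parse_stereo_tokens(self.name)


def build_species_ladder(
    compound: Compound,
    temperature: float = 298.15,
    constants: PhysicalConstants = CONSTANTS,
) -> list[ProtonationSpecies]:
    """Deprotonation ladder of a compound, anchored at the pH-0 major species.

    Species 0 is the major species (ΔG° = 0); species j, reached by removing
    j protons, has cumulative ΔG°_j = Σ_{i<=j} RT·ln10·pKa_i and charge and
    hydrogen count lowered by j.  Only pKa values inside :data:`PKA_WINDOW`
    generate species.
    """
    usable = [p for p in compound.pka_values if PKA_WINDOW[0] <= p <= PKA_WINDOW[1]]
    if len(usable) > compound.n_hydrogens:
        raise ValueError(
            f"{compound.id}: {len(usable)} pKa values but only "
            f"{compound.n_hydrogens} hydrogens to remove"
        )
    rt = constants.rt_kj(temperature)
    ladder = [
        ProtonationSpecies(
            charge=compound.charge, n_hydrogens=compound.n_hydrogens, dg0=0.0
        )
    ]
    cumulative = 0.0
    for j, pka in enumerate(usable, start=1):
        cumulative += rt * LN10 * pka
        ladder.append(
            ProtonationSpecies(
                charge=compound.charge - j,
                n_hydrogens=compound.n_hydrogens - j,
                dg0=cumulative,
            )
        )
    return ladder


def major_species_at_ph(
    ladder: Sequence[ProtonationSpecies],
    conditions: AqueousConditions,
    constants: PhysicalConstants = CONSTANTS,
    tolerance: float = 1e-9,
) -> int:
    """Index of the dominant species at the given conditions.

    Diagnostic helper: returns the argmin of the Legendre-transformed
    energies, breaking near-ties (within ``tolerance`` kJ/mol) toward the
    more protonated species.
    """
    if len(ladder) == 0:
        raise ValueError("species ladder is empty")
    energies = [
        legendre_transform_species(s, conditions, constants) for s in ladder
    ]
    best = min(energies)
    for idx, g in enumerate(energies):
        if g <= best + tolerance:
            return idx
    raise AssertionError("unreachable")
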