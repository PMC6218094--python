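"""Literature reference values for the TECRDB-derived redox compilation.

These tallies and category means are the published anchor points of the
calibrated quantum-chemistry workflow this package implements: the number of
experimentally measured potentials available per oxidoreductase category, the
number of enumerated candidate reactions per category over sub-7-carbon KEGG
metabolites, and the rounded mean E'^m of each category's predicted
distribution.  They are used as fixture design targets and consistency
checks, never as substitutes for computed values.
"""
from __future__ import annotations

__all__ = [
    "EXPERIMENTAL_COUNTS",
    "ENUMERATED_COUNTS",
    "CATEGORY_MEAN_MV",
    "ACTIVATION_SHIFT_MV",
    "NADP_STANDARD_POTENTIAL_V",
]

#: Experimentally measured potentials per category in the calibration set.
EXPERIMENTAL_COUNTS: dict[str, int] = {"G1": 8, "G2": 59, "G3": 23, "G4": 15}

#: Enumerated natural + non-natural reactions per category (< 7 carbons).
ENUMERATED_COUNTS: dict[str, int] = {"G1": 83, "G2": 205, "G3": 104, "G4": 260}

#: Rounded (nearest 5 mV) mean E'^m of each category's distribution.
CATEGORY_MEAN_MV: dict[str, float] = {
    "G1": -550.0,
    "G1-activated": -300.0,
    "G2": -225.0,
    "G3": -225.0,
    "G4": -15.0,
}

#: Conventional flat shift between activated and unactivated acid couples.
ACTIVATION_SHIFT_MV: float = 250.0

#: NAD(P) standard transformed potential at pH 7, I 0.25 M.
NADP_STANDARD_POTENTIAL_V: float = -0.330
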