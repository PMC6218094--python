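"""Rule-based enumeration of candidate two-electron redox pairs.

Compounds are described by integer functional-group count vectors over a
shared named basis.  A redox category is a sparse signature — the
product-minus-substrate group difference of its transformation — and every
ordered compound pair whose vector difference matches a signature is a
candidate reduction of that category.  Size, chirality-token and sugar-name
filters then remove chemically inconsistent candidates, mirroring how
hypothetical oxidoreductase reactions are mined from a metabolite database.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .speciation import Compound

__all__ = [
    "CategorySignature",
    "RedoxPair",
    "DEFAULT_SIGNATURES",
    "DEFAULT_SUGAR_FAMILIES",
    "match_pairs",
    "chirality_filter",
    "sugar_name_filter",
    "verify_pairs",
    "flag_natural",
]

logger = logging.getLogger(__name__)

#: Minimal functional-group basis sufficient to distinguish the four
#: oxidoreductase categories.
GROUP_BASIS = ("carboxylic_acid", "carbonyl", "hydroxycarbon", "amine")


@dataclass(frozen=True)
class CategorySignature:
    """Group-difference signature of one oxidoreductase category.

    ``group_delta`` maps functional-group names to the net product-minus-
    substrate count change of the reduction; ``co_reactants`` lists the
    implied co-substrates/products (H2 always implied, NH3 consumed for
    carbonyl-to-amine, H2O released where a C-O bond is broken).
    """

    category: str
    group_delta: Mapping[str, int]
    co_reactants: Mapping[str, int] = field(default_factory=dict)


#: Signatures written as reductions (oxidized -> reduced), two electrons.
DEFAULT_SIGNATURES: tuple[CategorySignature, ...] = (
    CategorySignature(
        "G1",
        {"carboxylic_acid": -1, "carbonyl": +1},
        {"h2": -1, "h2o": +1},
    ),
    CategorySignature(
        "G2",
        {"carbonyl": -1, "hydroxycarbon": +1},
        {"h2": -1},
    ),
    CategorySignature(
        "G3",
        {"carbonyl": -1, "amine": +1},
        {"h2": -1, "nh3": -1, "h2o": +1},
    ),
    CategorySignature(
        "G4",
        {"hydroxycarbon": -1},
        {"h2": -1, "h2o": +1},
    ),
)


@dataclass(frozen=True)
class RedoxPair:
    """An oxidized/reduced couple, stored in the direction of reduction."""

    substrate_id: str  # oxidized form
    product_id: str    # reduced form
    category: str
    n_electrons: int = 2
    natural: bool = False
    cofactor: str | None = None
    activated: bool = False

    def __post_init__(self) -> None:
        if self.substrate_id == self.product_id:
            raise ValueError("substrate and product must differ")
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")


def _basis_of(compounds: Sequence[Compound]) -> frozenset[str]:
    if not compounds:
        return frozenset()
    basis = frozenset(compounds[0].group_vector)
    for c in compounds[1:]:
        if frozenset(c.group_vector) != basis:
            raise ValueError(
                f"compound {c.id} uses a different functional-group basis"
            )
    return basis


def _delta_matches(
    substrate: Compound, product: Compound, signature: CategorySignature
) -> bool:
    keys = set(substrate.group_vector) | set(signature.group_delta)
    return all(
        product.group_vector.get(k, 0) - substrate.group_vector.get(k, 0)
        == signature.group_delta.get(k, 0)
        for k in keys
    )


def match_pairs(
    compounds: Sequence[Compound],
    signature: CategorySignature,
    max_carbons: int = 7,
) -> list[RedoxPair]:
    """All ordered pairs whose group-vector difference matches the signature.

    Both compounds must have fewer than ``max_carbons`` carbon atoms.
    Output is sorted by (substrate id, product id) for determinism.
    """
    _basis_of(compounds)
    small = [c for c in compounds if c.n_carbons < max_carbons]
    pairs = [
        RedoxPair(a.id, b.id, signature.category)
        for a in small
        for b in small
        if a.id != b.id and _delta_matches(a, b, signature)
    ]
    pairs.sort(key=lambda p: (p.substrate_id, p.product_id))
    return pairs


def _stereo_conflict(a: frozenset[str], b: frozenset[str]) -> bool:
    for family in ({"R", "S"}, {"L", "D"}):
        fa, fb = a & family, b & family
        if fa and fb and fa != fb:
            return True
    return False


def chirality_filter(
    pairs: Iterable[RedoxPair], compounds: Mapping[str, Compound]
) -> list[RedoxPair]:
    """Drop pairs whose substrate/product name stereo tokens conflict.

    A conflict is an R-vs-S or L-vs-D mismatch; pairs where either side
    carries no token of a family pass that family's check.
    """
    kept = []
    for pair in pairs:
        sub = compounds[pair.substrate_id].stereo_tokens
        prod = compounds[pair.product_id].stereo_tokens
        if _stereo_conflict(sub, prod):
            logger.debug(
                "chirality filter dropped %s -> %s (%s vs %s)",
                pair.substrate_id,
                pair.product_id,
                sorted(sub),
                sorted(prod),
            )
        else:
            kept.append(pair)
    return kept


#: Sugar carbon-skeleton name roots.  Reduction of a sugar must stay within
#: one family; stereo-token matching alone keeps wrong cross-family pairs
#: (e.g. an L-pentonate paired with an L-pentose of a different skeleton).
DEFAULT_SUGAR_FAMILIES: Mapping[str, tuple[str, ...]] = {
    "ribo": ("ribose", "ribonate", "ribonic", "ribitol", "ribulose"),
    "arabino": ("arabinose", "arabinonate", "arabinonic", "arabinitol", "arabitol"),
    "xylo": ("xylose", "xylonate", "xylonic", "xylitol", "xylulose"),
    "lyxo": ("lyxose", "lyxonate", "lyxonic", "lyxitol"),
    "gluco": ("glucose", "gluconate", "gluconic", "glucitol", "sorbitol"),
    "galacto": ("galactose", "galactonate", "galactonic", "galactitol"),
    "manno": ("mannose", "mannonate", "mannonic", "mannitol"),
}


def _sugar_family(
    name: str, families: Mapping[str, Sequence[str]]
) -> str | None:
    lowered = name.lower()
    best: tuple[int, str] | None = None
    for family, roots in families.items():
        for root in roots:
            if root in lowered and (best is None or len(root) > best[0]):
                best = (len(root), family)
    return best[1] if best else None


def sugar_name_filter(
    pairs: Iterable[RedoxPair],
    compounds: Mapping[str, Compound],
    families: Mapping[str, Sequence[str]] | None = None,
) -> list[RedoxPair]:
    """Drop pairs whose compound names belong to different sugar families.

    ``families`` maps a family label to the name roots that denote one sugar
    carbon skeleton; an empty mapping is the identity.  Rule hits are logged
    per pair.
    """
    if families is None:
        families = DEFAULT_SUGAR_FAMILIES
    kept = []
    for pair in pairs:
        fam_sub = _sugar_family(compounds[pair.substrate_id].name, families)
        fam_prod = _sugar_family(compounds[pair.product_id].name, families)
        if fam_sub is not None and fam_prod is not None and fam_sub != fam_prod:
            logger.info(
                "sugar-name filter dropped %s -> %s (%s vs %s)",
                pair.substrate_id,
                pair.product_id,
                fam_sub,
                fam_prod,
            )
        else:
            kept.append(pair)
    return kept


def verify_pairs(
    pairs: Iterable[RedoxPair],
    compounds: Mapping[str, Compound],
    signatures: Sequence[CategorySignature] = DEFAULT_SIGNATURES,
) -> None:
    """Independent post-hoc check that every pair satisfies its signature."""
    by_category = {s.category: s for s in signatures}
    for pair in pairs:
        signature = by_category[pair.category]
        if not _delta_matches(
            compounds[pair.substrate_id], compounds[pair.product_id], signature
        ):
            raise AssertionError(
                f"pair {pair.substrate_id} -> {pair.product_id} violates the "
                f"{pair.category} signature"
            )


def flag_natural(
    pairs: Iterable[RedoxPair],
    known_reactions: Iterable[tuple[str, str]],
) -> list[RedoxPair]:
    """Mark pairs that appear in a known enzymatic-reaction table."""
    known = {tuple(k) for k in known_reactions}
    return [
        RedoxPair(
            p.substrate_id,
            p.product_id,
            p.category,
            p.n_electrons,
            natural=(p.substrate_id, p.product_id) in known,
            cofactor=p.cofactor,
            activated=p.activated,
        )
        for p in pairs
    ]
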