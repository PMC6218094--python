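"""Reaction-fingerprint potential predictor.

The structural alternative to the quantum route: each compound is encoded
as its 166 MACCS substructure keys, a half-reaction as the concatenation of
substrate then product keys (332 bits), and potentials are regressed on the
bits with L1 (Lasso) regularisation — a sane match for small training sets,
where circular fingerprints would overfit.  One model is fit per
oxidoreductase category.  Compounds are fingerprinted from their pH-0
major-species structures, the only structures the data model carries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from sklearn.linear_model import Lasso, LassoCV, LinearRegression

__all__ = [
    "N_KEYS",
    "N_REACTION_BITS",
    "ReactionFingerprint",
    "FingerprintModel",
    "compound_keys",
    "reaction_fingerprint",
    "fit_fingerprint_regression",
]

N_KEYS = 166
N_REACTION_BITS = 2 * N_KEYS

#: Default regularisation grid for internal cross-validation (in volts per
#: bit these are mild penalties; the data are on the ~0.1 V scale).
DEFAULT_LAMBDA_GRID = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1)


@dataclass(frozen=True)
class ReactionFingerprint:
    """Concatenated substrate (bits 0-165) and product (bits 166-331) keys."""

    pair_id: str
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != N_REACTION_BITS:
            raise ValueError(
                f"{self.pair_id}: expected {N_REACTION_BITS} bits, "
                f"got {len(self.bits)}"
            )
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"{self.pair_id}: bits must be 0/1")


def compound_keys(smiles: str) -> np.ndarray:
    """MACCS 166-key binary vector of a structure.

    Uses the standard public key definitions; key i of the conventional
    1-based numbering lands at index i-1.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    bits = np.zeros(N_KEYS, dtype=np.uint8)
    for idx in fp.GetOnBits():
        if idx >= 1:
            bits[idx - 1] = 1
    return bits


def reaction_fingerprint(
    substrate_keys: Sequence[int],
    product_keys: Sequence[int],
    pair_id: str = "",
) -> ReactionFingerprint:
    """Concatenate substrate and product key vectors into a reaction fingerprint."""
    sub = np.asarray(substrate_keys)
    prod = np.asarray(product_keys)
    if sub.shape != (N_KEYS,) or prod.shape != (N_KEYS,):
        raise ValueError(
            f"substrate/product key vectors must have length {N_KEYS}"
        )
    bits = tuple(int(b) for b in np.concatenate([sub, prod]))
    return ReactionFingerprint(pair_id=pair_id, bits=bits)


@dataclass(frozen=True)
class FingerprintModel:
    """Fitted sparse linear model: potential = weights · bits + intercept."""

    weights: tuple[float, ...]
    intercept: float
    regularization: float
    n_train: int

    def predict(self, fingerprints: Sequence[ReactionFingerprint]) -> np.ndarray:
        x = np.array([fp.bits for fp in fingerprints], dtype=float)
        return x @ np.asarray(self.weights) + self.intercept


def fit_fingerprint_regression(
    fingerprints: Sequence[ReactionFingerprint],
    potentials: Sequence[float],
    regularization: float | None = None,
    seed: int = 0,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    cv_folds: int = 5,
) -> FingerprintModel:
    """L1-regularised least squares of potentials on reaction bits.

    ``regularization`` is the Lasso penalty λ (scikit-learn's ``alpha``);
    ``None`` selects it by ``cv_folds``-fold cross-validation over
    ``lambda_grid`` on the training category, and exactly 0 falls back to
    unregularised least squares.  Deterministic given seed and λ, and
    invariant to training-row order.
    """
    if regularization is not None and regularization < 0:
        raise ValueError(f"regularization must be >= 0, got {regularization}")
    if len(fingerprints) < 2:
        raise ValueError("need at least two training pairs")
    if len(fingerprints) != len(potentials):
        raise ValueError("fingerprints and potentials must be aligned")
    x = np.array([fp.bits for fp in fingerprints], dtype=float)
    y = np.asarray(potentials, dtype=float)

    if regularization == 0:
        model = LinearRegression().fit(x, y)
        lam = 0.0
    elif regularization is None:
        folds = min(cv_folds, len(y))
        cv = LassoCV(
            alphas=list(lambda_grid),
            cv=folds,
            random_state=seed,
            max_iter=100_000,
        ).fit(x, y)
        lam = float(cv.alpha_)
        model = cv
    else:
        lam = float(regularization)
        model = Lasso(alpha=lam, max_iter=100_000, random_state=seed).fit(x, y)

    weights = np.atleast_1d(model.coef_)
    return FingerprintModel(
        weights=tuple(float(w) for w in weights),
        intercept=float(model.intercept_),
        regularization=lam,
        n_train=len(y),
    )
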