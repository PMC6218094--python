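"""Per-category linear calibration and cross-method outlier detection.

Raw predicted potentials carry systematic error (chiefly from neglected
vibrational enthalpy/entropy), so each oxidoreductase category gets a
two-parameter ordinary-least-squares calibration of experiment on raw
prediction.  Prediction errors from two independent methods, normalised to
z-scores, jointly flag experimental records that are likely mistabulated:
a record both methods miss by more than the threshold is suspect.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ExperimentalRecord",
    "CalibrationModel",
    "VALID_CATEGORIES",
    "fit_calibration",
    "evaluate_predictions",
    "error_zscores",
    "joint_outliers",
]

VALID_CATEGORIES = frozenset({"G1", "G1-activated", "G2", "G3", "G4"})


@dataclass(frozen=True)
class ExperimentalRecord:
    """One experimentally measured E'^m (V) with its category and source."""

    pair_id: str
    category: str
    e_prime_m: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not math.isfinite(self.e_prime_m):
            raise ValueError(f"{self.pair_id}: potential must be finite")


@dataclass(frozen=True)
class CalibrationModel:
    """Two-parameter calibration: calibrated = slope*raw + intercept (V)."""

    category: str
    slope: float
    intercept: float
    n_train: int
    mae: float
    pearson_r: float
    r_squared: float

    def predict(self, raw):
        return self.slope * np.asarray(raw, dtype=float) + self.intercept


def fit_calibration(
    raw_predictions: Mapping[str, float],
    experimental: Sequence[ExperimentalRecord],
    category: str,
) -> CalibrationModel:
    """Ordinary least squares of experiment on raw prediction, one category.

    Records are paired by id; activated-acid records share the G1 model.
    Requires at least two pairs and non-degenerate raw values.
    """
    wanted = {category}
    if category == "G1":
        wanted.add("G1-activated")
    records = [
        r for r in experimental if r.category in wanted and r.pair_id in raw_predictions
    ]
    if len(records) < 2:
        raise ValueError(
            f"category {category}: need >= 2 paired observations, "
            f"got {len(records)}"
        )
    raw = np.array([raw_predictions[r.pair_id] for r in records])
    exp = np.array([r.e_prime_m for r in records])
    if np.ptp(raw) == 0:
        raise ValueError(f"category {category}: raw predictions have zero variance")
    slope, intercept = np.polyfit(raw, exp, 1)
    calibrated = slope * raw + intercept
    metrics = evaluate_predictions(calibrated, exp)
    return CalibrationModel(
        category=category,
        slope=float(slope),
        intercept=float(intercept),
        n_train=len(records),
        mae=metrics["mae"],
        pearson_r=metrics["pearson_r"],
        r_squared=metrics["r_squared"],
    )


def evaluate_predictions(
    predictions: Sequence[float], experimental: Sequence[float]
) -> dict[str, float]:
    """MAE (V), Pearson r and R² = 1 - SS_res/SS_tot of predictions.

    R² is relative to the mean predictor and may be negative.  A constant
    experimental vector leaves Pearson r (and R²) undefined; they are
    reported as NaN rather than raised.
    """
    pred = np.asarray(predictions, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape or pred.size < 2:
        raise ValueError("predictions and experiment must be equal length >= 2")
    mae = float(np.mean(np.abs(pred - exp)))
    ss_res = float(np.sum((exp - pred) ** 2))
    ss_tot = float(np.sum((exp - exp.mean()) ** 2))
    if ss_tot == 0:
        return {"mae": mae, "pearson_r": float("nan"), "r_squared": float("nan")}
    r_squared = 1.0 - ss_res / ss_tot
    if np.ptp(pred) == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(pred, exp)[0, 1])
    return {"mae": mae, "pearson_r": pearson, "r_squared": r_squared}


def error_zscores(errors: Sequence[float]) -> np.ndarray:
    """Z-scores of prediction errors, (err - mean)/sd with the sample sd (ddof=1)."""
    err = np.asarray(errors, dtype=float)
    if err.size < 2:
        raise ValueError("need at least two errors")
    sd = err.std(ddof=1)
    if sd == 0 or np.ptp(err) == 0:
        raise ValueError("errors have zero spread; z-scores undefined")
    return (err - err.mean()) / sd


def joint_outliers(
    pair_ids: Sequence[str],
    z_method1: Sequence[float],
    z_method2: Sequence[float],
    threshold: float = 2.0,
) -> list[str]:
    """Ids whose |z| exceeds the threshold for *both* prediction methods.

    Consistent large deviation from two independent predictors marks the
    experimental value, not the predictions, as the likely error.
    """
    z1 = np.asarray(z_method1, dtype=float)
    z2 = np.asarray(z_method2, dtype=float)
    if not (len(pair_ids) == z1.size == z2.size):
        raise ValueError("pair_ids and z-score vectors must be aligned")
    mask = (np.abs(z1) > threshold) & (np.abs(z2) > threshold)
    return [pid for pid, m in zip(pair_ids, mask) if m]
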