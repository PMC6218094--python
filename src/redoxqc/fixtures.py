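"""Deterministic synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here without downloads:

* a toy compound set with hand-assigned functional-group vectors, stereo
  names and sugar-family names, containing planted matches for all four
  oxidoreductase signatures, a seven-carbon exclusion case, a chirality
  conflict and a known-wrong cross-family sugar pair;
* conformer electronic-energy ensembles constructed so that their exact
  Boltzmann mean (computed by direct summation, independently of the
  pipeline's log-sum-exp path) is prescribed, with pair-wise target
  potentials drawn around the literature category means;
* per-category calibration sets drawn from a prescribed affine law
  experiment = slope*raw + intercept + N(0, noise), sized like the
  experimental compilation (G1 8, G2 59, G3 23, G4 15);
* a cross-method error set with one planted joint outlier whose recovery is
  guaranteed (background errors are bounded, the planted one is not);
* a two-subgroup potential set with a planted mean offset for the Welch
  comparison.

All randomness flows through one seeded generator; identical seeds produce
byte-identical files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from . import reference
from .calibration import ExperimentalRecord
from .enumeration import GROUP_BASIS, RedoxPair
from .qc import ConformerEnergySet, ReferenceEnergies
from .speciation import Compound
from .thermo import CONSTANTS

__all__ = [
    "FixtureBundle",
    "toy_compounds",
    "planted_reactions",
    "make_conformer_ensemble",
    "make_calibration_set",
    "make_outlier_set",
    "make_subgroup_set",
    "generate_fixture_bundle",
    "write_fixtures",
]

#: H2 electronic energy (Hartree) used by the synthetic model chemistry.
H2_ENERGY_HARTREE = -1.17
MODEL_CHEMISTRY = "synthetic-spe"

#: Affine law of the synthetic calibration sets: experiment =
#: slope*raw + intercept (V) + Gaussian noise (V).
CALIBRATION_SLOPE = 0.8
CALIBRATION_INTERCEPT = 0.030
CALIBRATION_NOISE_V = 0.010

_GV = dict.fromkeys(GROUP_BASIS, 0)


def _gv(**counts: int) -> dict[str, int]:
    vec = dict(_GV)
    vec.update(counts)
    return vec


def toy_compounds() -> list[Compound]:
    """Hand-assigned compound set over the default functional-group basis."""
    return [
        Compound("acid1", "Acetate", "CC(=O)O", 0, 4, 2, (4.76,), _gv(carboxylic_acid=1)),
        Compound("ald1", "Acetaldehyde", "CC=O", 0, 4, 2, (), _gv(carbonyl=1)),
        Compound("alc1", "Ethanol", "CCO", 0, 6, 2, (), _gv(hydroxycarbon=1)),
        Compound("amine1", "Ethylamine", "CCN", 0, 7, 2, (10.6,), _gv(amine=1)),
        Compound("hc1", "Ethane", "CC", 0, 6, 2, (), _gv()),
        Compound("ald2", "Propanal", "CCC=O", 0, 6, 3, (), _gv(carbonyl=1)),
        Compound("alc2", "1-Propanol", "CCCO", 0, 8, 3, (), _gv(hydroxycarbon=1)),
        Compound("amine2", "Propylamine", "CCCN", 0, 9, 3, (10.5,), _gv(amine=1)),
        Compound("hc2", "Propane", "CCC", 0, 8, 3, (), _gv()),
        Compound("rald", "(R)-2-Hydroxypropanal", "C[C@@H](O)C=O", 0, 6, 3, (),
                 _gv(carbonyl=1, hydroxycarbon=1)),
        Compound("rdiol", "(R)-1,2-Propanediol", "C[C@@H](O)CO", 0, 8, 3, (),
                 _gv(hydroxycarbon=2)),
        Compound("sdiol", "(S)-1,2-Propanediol", "C[C@H](O)CO", 0, 8, 3, (),
                 _gv(hydroxycarbon=2)),
        Compound("xylonate", "L-Xylonate", "OCC(O)C(O)C(O)C(=O)O", 0, 10, 5, (3.5,),
                 _gv(carboxylic_acid=1, hydroxycarbon=3)),
        Compound("xylose", "L-Xylose", "OCC(O)C(O)C(O)C=O", 0, 10, 5, (),
                 _gv(carbonyl=1, hydroxycarbon=3)),
        Compound("arabinose", "L-Arabinose", "OCC(O)C(O)C(O)C=O", 0, 10, 5, (),
                 _gv(carbonyl=1, hydroxycarbon=3)),
        Compound("xylitol", "Xylitol", "OCC(O)C(O)C(O)CO", 0, 12, 5, (),
                 _gv(hydroxycarbon=4)),
        Compound("bigald", "Heptanal", "CCCCCCC=O", 0, 14, 7, (), _gv(carbonyl=1)),
        Compound("bigalc", "1-Heptanol", "CCCCCCCO", 0, 16, 7, (),
                 _gv(hydroxycarbon=1)),
    ]


def planted_reactions() -> list[RedoxPair]:
    """The intended reduction pairs of the toy set (two or more per category)."""
    return [
        RedoxPair("acid1", "ald1", "G1"),
        RedoxPair("xylonate", "xylose", "G1"),
        RedoxPair("ald1", "alc1", "G2"),
        RedoxPair("ald2", "alc2", "G2"),
        RedoxPair("rald", "rdiol", "G2"),
        RedoxPair("xylose", "xylitol", "G2"),
        RedoxPair("ald1", "amine1", "G3"),
        RedoxPair("ald2", "amine2", "G3"),
        RedoxPair("alc1", "hc1", "G4"),
        RedoxPair("alc2", "hc2", "G4"),
    ]


def _direct_boltzmann_mean(
    energies: Sequence[float], temperature: float = 298.15
) -> float:
    """Independent direct-summation Boltzmann mean (Hartree)."""
    rt = CONSTANTS.rt_kj(temperature)
    e_min = min(energies)
    weights = [
        math.exp(-(e - e_min) * CONSTANTS.hartree_to_kj_per_mol / rt)
        for e in energies
    ]
    z = sum(weights)
    return sum(w * e for w, e in zip(weights, energies)) / z


def make_conformer_ensemble(
    rng: np.random.Generator,
    compound_id: str,
    target_mean_hartree: float,
    n_conformers: int | None = None,
    spread_kj: float = 8.0,
    temperature: float = 298.15,
) -> tuple[ConformerEnergySet, float]:
    """Ensemble whose exact Boltzmann mean equals ``target_mean_hartree``.

    Conformer gaps are drawn uniformly in [0, spread_kj] kJ/mol (the lowest
    conformer at 0), then the whole ensemble is shifted so the direct-sum
    Boltzmann mean lands on the target.  Returns the ensemble and the target
    (= true) mean.
    """
    if n_conformers is None:
        n_conformers = int(rng.integers(3, 11))
    gaps_kj = np.concatenate([[0.0], rng.uniform(0.0, spread_kj, n_conformers - 1)])
    gaps_ha = gaps_kj / CONSTANTS.hartree_to_kj_per_mol
    mean_gap = _direct_boltzmann_mean(gaps_ha.tolist(), temperature)
    energies = tuple(float(g - mean_gap + target_mean_hartree) for g in gaps_ha)
    ensemble = ConformerEnergySet(compound_id, energies, MODEL_CHEMISTRY)
    return ensemble, target_mean_hartree


def _target_potentials(
    rng: np.random.Generator, reactions: Sequence[RedoxPair], sigma_v: float = 0.05
) -> dict[str, float]:
    """Per-pair target E°(MS, pH 0) around the literature category means."""
    return {
        f"{p.substrate_id}__{p.product_id}": float(
            rng.normal(reference.CATEGORY_MEAN_MV[p.category] / 1000.0, sigma_v)
        )
        for p in reactions
    }


def _assign_compound_means(
    rng: np.random.Generator,
    reactions: Sequence[RedoxPair],
    targets: Mapping[str, float],
) -> dict[str, float]:
    """Walk the reaction graph assigning Boltzmann-mean electronic energies.

    Substrate means are drawn freely; each product mean is then fixed so the
    pair's electronic-energy difference reproduces its target potential,
    ΔE = -nF·E°.  Already-assigned compounds are reused, so later pairs
    sharing a compound get an implied (recorded) rather than target E°.
    """
    means: dict[str, float] = {}
    for pair in reactions:
        if pair.substrate_id not in means:
            means[pair.substrate_id] = float(rng.uniform(-500.0, -100.0))
        if pair.product_id not in means:
            e_target = targets[f"{pair.substrate_id}__{pair.product_id}"]
            delta_kj = -e_target * pair.n_electrons * CONSTANTS.F / 1000.0
            means[pair.product_id] = (
                means[pair.substrate_id]
                + H2_ENERGY_HARTREE
                + delta_kj / CONSTANTS.hartree_to_kj_per_mol
            )
    return means


def make_calibration_set(
    rng: np.random.Generator,
    n: int,
    category: str = "G2",
    slope: float = CALIBRATION_SLOPE,
    intercept: float = CALIBRATION_INTERCEPT,
    noise_v: float = CALIBRATION_NOISE_V,
    center_v: float | None = None,
    spread_v: float = 0.060,
    prefix: str = "CAL",
) -> tuple[dict[str, float], list[ExperimentalRecord]]:
    """Raw predictions and matching experimental records from an affine law."""
    if center_v is None:
        center_v = reference.CATEGORY_MEAN_MV.get(category, -225.0) / 1000.0
    raw = rng.normal(center_v, spread_v, n)
    exp = slope * raw + intercept + rng.normal(0.0, noise_v, n)
    ids = [f"{prefix}_{category}_{i:03d}" for i in range(n)]
    raw_map = {pid: float(r) for pid, r in zip(ids, raw)}
    records = [
        ExperimentalRecord(pid, category, float(e), source="synthetic")
        for pid, e in zip(ids, exp)
    ]
    return raw_map, records


def make_outlier_set(
    rng: np.random.Generator,
    n: int = 59,
    sigma_v: float = 0.020,
    planted_sigmas: float = 4.0,
) -> dict:
    """Cross-method prediction errors with one planted joint outlier.

    Background errors are uniform on [-sigma, sigma] in both methods, so
    after z-scoring no background point can exceed sqrt(3) ~ 1.73; the
    planted record deviates by ``planted_sigmas``*sigma in both methods and
    is always, and alone, flagged at the conventional |z| > 2 threshold.
    """
    ids = [f"OUT_G2_{i:03d}" for i in range(n)]
    planted_id = ids[n // 2]
    err1 = rng.uniform(-sigma_v, sigma_v, n)
    err2 = rng.uniform(-sigma_v, sigma_v, n)
    idx = n // 2
    err1[idx] = planted_sigmas * sigma_v
    err2[idx] = planted_sigmas * sigma_v
    exp = rng.normal(-0.225, 0.050, n)
    return {
        "ids": ids,
        "planted_id": planted_id,
        "errors_qc": err1,
        "errors_fp": err2,
        "experimental": {pid: float(e) for pid, e in zip(ids, exp)},
        "pred_qc": {pid: float(e - d) for pid, e, d in zip(ids, exp, err1)},
        "pred_fp": {pid: float(e - d) for pid, e, d in zip(ids, exp, err2)},
    }


def make_subgroup_set(
    rng: np.random.Generator,
    n_per_group: int = 40,
    offset_v: float = 0.030,
    sigma_v: float = 0.020,
    center_v: float = -0.225,
    axis: str = "neighbor_group",
) -> dict:
    """Two labelled subgroups with a planted mean-potential offset."""
    potentials: dict[str, float] = {}
    labels: dict[str, str] = {}
    for i, e in enumerate(rng.normal(center_v + offset_v / 2, sigma_v, n_per_group)):
        pid = f"SUB_A_{i:03d}"
        potentials[pid] = float(e)
        labels[pid] = "ketoacid"
    for i, e in enumerate(rng.normal(center_v - offset_v / 2, sigma_v, n_per_group)):
        pid = f"SUB_B_{i:03d}"
        potentials[pid] = float(e)
        labels[pid] = "hydroxyl"
    return {
        "axis": axis,
        "offset_v": offset_v,
        "potentials": potentials,
        "labels": labels,
    }


@dataclass
class FixtureBundle:
    """Everything generated for one seed, plus the planted ground truth."""

    seed: int
    compounds: list[Compound]
    reactions: list[RedoxPair]
    ensembles: list[ConformerEnergySet]
    references: ReferenceEnergies
    boltzmann_means: dict[str, float]
    target_potentials: dict[str, float]
    calibration_raw: dict[str, float] = field(default_factory=dict)
    experimental: list[ExperimentalRecord] = field(default_factory=list)
    outliers: dict = field(default_factory=dict)
    subgroups: dict = field(default_factory=dict)


def generate_fixture_bundle(seed: int) -> FixtureBundle:
    """Generate the full synthetic study: compounds, energies, calibration
    sets, outlier set and subgroup set, all from one seeded generator."""
    rng = np.random.default_rng(seed)
    compounds = toy_compounds()
    reactions = planted_reactions()
    targets = _target_potentials(rng, reactions)
    means = _assign_compound_means(rng, reactions, targets)
    # compounds that never enter a reaction still get ensembles
    for compound in compounds:
        if compound.id not in means:
            means[compound.id] = float(rng.uniform(-500.0, -100.0))
    ensembles = []
    boltzmann_means = {}
    for compound in compounds:
        ensemble, true_mean = make_conformer_ensemble(rng, compound.id, means[compound.id])
        ensembles.append(ensemble)
        boltzmann_means[compound.id] = true_mean

    calibration_raw: dict[str, float] = {}
    experimental: list[ExperimentalRecord] = []
    for category, n in sorted(reference.EXPERIMENTAL_COUNTS.items()):
        raw_map, records = make_calibration_set(rng, n, category)
        calibration_raw.update(raw_map)
        experimental.extend(records)
    # experimental records for the planted pipeline pairs, from the same law
    for pair in reactions:
        pid = f"{pair.substrate_id}__{pair.product_id}"
        e_exp = (
            CALIBRATION_SLOPE * targets[pid]
            + CALIBRATION_INTERCEPT
            + float(rng.normal(0.0, CALIBRATION_NOISE_V))
        )
        experimental.append(
            ExperimentalRecord(pid, pair.category, e_exp, source="synthetic")
        )

    outliers = make_outlier_set(rng)
    subgroups = make_subgroup_set(rng)
    return FixtureBundle(
        seed=seed,
        compounds=compounds,
        reactions=reactions,
        ensembles=ensembles,
        references=ReferenceEnergies({MODEL_CHEMISTRY: H2_ENERGY_HARTREE}),
        boltzmann_means=boltzmann_means,
        target_potentials=targets,
        calibration_raw=calibration_raw,
        experimental=experimental,
        outliers=outliers,
        subgroups=subgroups,
    )


def write_fixtures(bundle: FixtureBundle, outdir) -> dict[str, Path]:
    """Write the bundle as CSV tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": outdir / "compounds.csv",
        "energies": outdir / "energies.csv",
        "h2_reference": outdir / "h2_reference.csv",
        "reactions": outdir / "reactions.csv",
        "experimental": outdir / "experimental.csv",
        "calibration_raw": outdir / "calibration_raw.csv",
        "outlier_pred_qc": outdir / "outlier_pred_qc.csv",
        "outlier_pred_fp": outdir / "outlier_pred_fp.csv",
        "outlier_experimental": outdir / "outlier_experimental.csv",
        "subgroup_potentials": outdir / "subgroup_potentials.csv",
        "labels": outdir / "labels.csv",
    }
    rio.write_compound_table(bundle.compounds, paths["compounds"])
    rio.write_energy_table(bundle.ensembles, paths["energies"])
    rio.write_reference_energies(bundle.references, paths["h2_reference"])
    rio.write_reaction_table(bundle.reactions, paths["reactions"])
    rio.write_experimental_table(bundle.experimental, paths["experimental"])

    def _potential_csv(mapping: Mapping[str, float], path: Path) -> None:
        pd.DataFrame(
            {
                "pair_id": list(mapping),
                "e_prime_m_volts": ["%.17g" % v for v in mapping.values()],
            }
        ).to_csv(path, index=False)

    _potential_csv(bundle.calibration_raw, paths["calibration_raw"])
    _potential_csv(bundle.outliers["pred_qc"], paths["outlier_pred_qc"])
    _potential_csv(bundle.outliers["pred_fp"], paths["outlier_pred_fp"])
    rio.write_experimental_table(
        [
            ExperimentalRecord(pid, "G2", e, source="synthetic")
            for pid, e in bundle.outliers["experimental"].items()
        ],
        paths["outlier_experimental"],
    )
    _potential_csv(bundle.subgroups["potentials"], paths["subgroup_potentials"])
    rio.write_label_table(
        {bundle.subgroups["axis"]: bundle.subgroups["labels"]}, paths["labels"]
    )
    return paths
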