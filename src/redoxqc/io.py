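"""Delimited-table readers/writers and run configuration.

CSV with a header row is the canonical dialect for every table in the
pipeline: compound tables (structure, charge/proton bookkeeping, pKa ladder,
group vector), per-conformer electronic-energy tables, experimental
potential tables, reaction (redox-pair) tables and subgroup label tables.
Energies are serialised at 17 significant digits so round-trips are exact.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .calibration import CalibrationModel, ExperimentalRecord
from .enumeration import RedoxPair
from .qc import ConformerEnergySet, ReferenceEnergies
from .speciation import Compound
from .thermo import AqueousConditions, PotentialEstimate

__all__ = [
    "RunConfig",
    "read_compound_table",
    "write_compound_table",
    "read_energy_table",
    "write_energy_table",
    "read_reference_energies",
    "write_reference_energies",
    "read_experimental_table",
    "write_experimental_table",
    "read_reaction_table",
    "write_reaction_table",
    "read_label_table",
    "write_label_table",
    "write_estimates",
    "read_estimates",
    "write_calibration_models",
    "read_calibration_models",
]

_FLOAT_FMT = "%.17g"

COMPOUND_COLUMNS = [
    "id",
    "name",
    "smiles",
    "charge",
    "n_hydrogens",
    "n_carbons",
    "pka_list",
    "group_vector",
]
ENERGY_COLUMNS = ["compound_id", "conformer_index", "model_chemistry", "energy_hartree"]
MAX_EXPECTED_CONFORMERS = 10


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_compound_table(
    path, validate_smiles: bool = False
) -> tuple[list[Compound], list[str]]:
    """Read a compound table; returns (compounds, error report).

    Malformed rows (bad numbers, bad group-vector JSON, and — when
    ``validate_smiles`` — unparseable SMILES) are collected into the error
    report with their line numbers instead of being silently dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, COMPOUND_COLUMNS, path)
    compounds: list[Compound] = []
    errors: list[str] = []
    for row_idx, row in df.iterrows():
        line = row_idx + 2  # header is line 1
        try:
            pka = tuple(
                float(p) for p in str(row["pka_list"]).split(";") if p.strip()
            )
            group_vector = (
                json.loads(row["group_vector"]) if row["group_vector"] else {}
            )
            compound = Compound(
                id=row["id"],
                name=row["name"],
                smiles=row["smiles"],
                charge=int(row["charge"]),
                n_hydrogens=int(row["n_hydrogens"]),
                n_carbons=int(row["n_carbons"]),
                pka_values=pka,
                group_vector={str(k): int(v) for k, v in group_vector.items()},
            )
        except (ValueError, json.JSONDecodeError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        if validate_smiles and compound.smiles:
            from rdkit import Chem

            if Chem.MolFromSmiles(compound.smiles) is None:
                errors.append(
                    f"line {line}: unparseable SMILES {compound.smiles!r}"
                )
                continue
        compounds.append(compound)
    return compounds, errors


def write_compound_table(compounds: Iterable[Compound], path) -> None:
    rows = [
        {
            "id": c.id,
            "name": c.name,
            "smiles": c.smiles,
            "charge": c.charge,
            "n_hydrogens": c.n_hydrogens,
            "n_carbons": c.n_carbons,
            "pka_list": ";".join(_FLOAT_FMT % p for p in c.pka_values),
            "group_vector": json.dumps(dict(c.group_vector), sort_keys=True),
        }
        for c in compounds
    ]
    pd.DataFrame(rows, columns=COMPOUND_COLUMNS).to_csv(path, index=False)


def read_energy_table(path) -> list[ConformerEnergySet]:
    """Read per-conformer energies, grouped per (compound, model chemistry).

    A non-numeric energy cell is an error naming its line; a compound with
    more than 10 conformers only warns (larger ensembles are unusual but
    legitimate).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ENERGY_COLUMNS, path)
    parsed = []
    for row_idx, row in df.iterrows():
        try:
            energy = float(row["energy_hartree"])
        except ValueError:
            raise ValueError(
                f"{path}: line {row_idx + 2}: non-numeric energy "
                f"{row['energy_hartree']!r}"
            ) from None
        parsed.append(
            (row["compound_id"], row["model_chemistry"], int(row["conformer_index"]), energy)
        )
    grouped: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for compound_id, chemistry, idx, energy in parsed:
        grouped.setdefault((compound_id, chemistry), []).append((idx, energy))
    ensembles = []
    for (compound_id, chemistry), entries in grouped.items():
        if len(entries) > MAX_EXPECTED_CONFORMERS:
            warnings.warn(
                f"{compound_id} ({chemistry}): {len(entries)} conformers "
                f"(more than the expected {MAX_EXPECTED_CONFORMERS})",
                stacklevel=2,
            )
        entries.sort(key=lambda pair: pair[0])
        ensembles.append(
            ConformerEnergySet(
                compound_id=compound_id,
                energies=tuple(e for _, e in entries),
                model_chemistry=chemistry,
            )
        )
    return ensembles


def write_energy_table(ensembles: Iterable[ConformerEnergySet], path) -> None:
    rows = [
        {
            "compound_id": ens.compound_id,
            "conformer_index": i,
            "model_chemistry": ens.model_chemistry,
            "energy_hartree": _FLOAT_FMT % e,
        }
        for ens in ensembles
        for i, e in enumerate(ens.energies)
    ]
    pd.DataFrame(rows, columns=ENERGY_COLUMNS).to_csv(path, index=False)


def read_reference_energies(path) -> ReferenceEnergies:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["model_chemistry", "h2_energy_hartree"], path)
    return ReferenceEnergies(
        h2_energy={
            str(r.model_chemistry): float(r.h2_energy_hartree)
            for r in df.itertuples()
        }
    )


def write_reference_energies(references: ReferenceEnergies, path) -> None:
    rows = [
        {"model_chemistry": k, "h2_energy_hartree": _FLOAT_FMT % v}
        for k, v in sorted(references.h2_energy.items())
    ]
    pd.DataFrame(rows, columns=["model_chemistry", "h2_energy_hartree"]).to_csv(
        path, index=False
    )


def read_experimental_table(path) -> list[ExperimentalRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["pair_id", "category", "e_prime_m_volts"], path)
    source = df["source"] if "source" in df.columns else [""] * len(df)
    return [
        ExperimentalRecord(
            pair_id=str(r["pair_id"]),
            category=str(r["category"]),
            e_prime_m=float(r["e_prime_m_volts"]),
            source=str(s),
        )
        for (_, r), s in zip(df.iterrows(), source)
    ]


def write_experimental_table(records: Iterable[ExperimentalRecord], path) -> None:
    rows = [
        {
            "pair_id": r.pair_id,
            "category": r.category,
            "e_prime_m_volts": _FLOAT_FMT % r.e_prime_m,
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["pair_id", "category", "e_prime_m_volts", "source"]
    ).to_csv(path, index=False)


def read_reaction_table(path) -> list[RedoxPair]:
    df = pd.read_csv(path)
    _require_columns(df, ["substrate_id", "product_id", "category"], path)
    pairs = []
    for _, r in df.iterrows():
        pairs.append(
            RedoxPair(
                substrate_id=str(r["substrate_id"]),
                product_id=str(r["product_id"]),
                category=str(r["category"]),
                natural=bool(r["natural"]) if "natural" in df.columns else False,
                activated=bool(r["activated"]) if "activated" in df.columns else False,
            )
        )
    return pairs


def write_reaction_table(pairs: Iterable[RedoxPair], path) -> None:
    rows = [
        {
            "pair_id": f"{p.substrate_id}__{p.product_id}",
            "substrate_id": p.substrate_id,
            "product_id": p.product_id,
            "category": p.category,
            "natural": p.natural,
            "activated": p.activated,
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "substrate_id",
            "product_id",
            "category",
            "natural",
            "activated",
        ],
    ).to_csv(path, index=False)


def read_label_table(path) -> dict[str, dict[str, str]]:
    """Long-format subgroup labels: axis -> {pair id -> label}."""
    df = pd.read_csv(path)
    _require_columns(df, ["pair_id", "axis", "label"], path)
    out: dict[str, dict[str, str]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["axis"]), {})[str(r["pair_id"])] = str(r["label"])
    return out


def write_label_table(labels: Mapping[str, Mapping[str, str]], path) -> None:
    rows = [
        {"pair_id": pid, "axis": axis, "label": label}
        for axis in sorted(labels)
        for pid, label in sorted(labels[axis].items())
    ]
    pd.DataFrame(rows, columns=["pair_id", "axis", "label"]).to_csv(path, index=False)


def write_estimates(estimates: Iterable[PotentialEstimate], path) -> None:
    rows = [
        {
            "pair_id": e.pair_id,
            "e_standard_ph0_volts": _FLOAT_FMT % e.e_standard_ph0,
            "e_prime_standard_volts": _FLOAT_FMT % e.e_prime_standard,
            "e_prime_m_volts": "" if e.e_prime_m is None else _FLOAT_FMT % e.e_prime_m,
            "method": e.method,
            "ph": e.conditions.ph,
            "ionic_strength": e.conditions.ionic_strength,
            "temperature": e.conditions.temperature,
            "standard_concentration_molar": e.conditions.standard_concentration,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_estimates(path) -> list[PotentialEstimate]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    estimates = []
    for _, r in df.iterrows():
        cond = AqueousConditions(
            ph=float(r["ph"]),
            ionic_strength=float(r["ionic_strength"]),
            temperature=float(r["temperature"]),
            standard_concentration=float(r["standard_concentration_molar"]),
        )
        e_m = r["e_prime_m_volts"]
        estimates.append(
            PotentialEstimate(
                pair_id=str(r["pair_id"]),
                e_standard_ph0=float(r["e_standard_ph0_volts"]),
                e_prime_standard=float(r["e_prime_standard_volts"]),
                e_prime_m=None if e_m == "" else float(e_m),
                method=str(r["method"]),
                conditions=cond,
            )
        )
    return estimates


def write_calibration_models(models: Iterable[CalibrationModel], path) -> None:
    """Serialise calibration models as plain-text key=value records."""
    lines = []
    for m in models:
        lines.append(
            " ".join(
                [
                    f"category={m.category}",
                    f"slope={_FLOAT_FMT % m.slope}",
                    f"intercept={_FLOAT_FMT % m.intercept}",
                    f"n_train={m.n_train}",
                    f"mae={_FLOAT_FMT % m.mae}",
                    f"pearson_r={_FLOAT_FMT % m.pearson_r}",
                    f"r_squared={_FLOAT_FMT % m.r_squared}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration_models(path) -> dict[str, CalibrationModel]:
    models = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        kv = dict(token.split("=", 1) for token in line.split())
        models[kv["category"]] = CalibrationModel(
            category=kv["category"],
            slope=float(kv["slope"]),
            intercept=float(kv["intercept"]),
            n_train=int(kv["n_train"]),
            mae=float(kv["mae"]),
            pearson_r=float(kv["pearson_r"]),
            r_squared=float(kv["r_squared"]),
        )
    return models


@dataclass(frozen=True)
class RunConfig:
    """Resolved run configuration; fully serialisable to YAML."""

    ph: float = 7.0
    ionic_strength: float = 0.25
    temperature: float = 298.15
    standard_concentration_molar: float = 0.001
    activation_offset_v: float = 0.250
    outlier_threshold: float = 2.0
    lasso_grid: tuple[float, ...] = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1)
    seed: int = 0

    def conditions(self) -> AqueousConditions:
        return AqueousConditions(
            ph=self.ph,
            ionic_strength=self.ionic_strength,
            temperature=self.temperature,
            standard_concentration=self.standard_concentration_molar,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(self.as_yaml())

    def as_yaml(self) -> str:
        data = asdict(self)
        data["lasso_grid"] = list(data["lasso_grid"])
        return yaml.safe_dump(data, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.as_yaml().encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "lasso_grid" in data:
            data["lasso_grid"] = tuple(data["lasso_grid"])
        return cls(**data)
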