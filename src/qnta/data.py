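"""Domain types and tabular I/O for calibration datasets.

The data layout is long ("tidy"): one row per replicate injection of one
chemical at one calibration level.  Two CSV files describe an experiment:

``chemicals.csv``
    chemical_id, name, retention_time, ionizing_group, chain_length,
    internal_standard_id
``calibration.csv``
    chemical_id, level_index, true_concentration, replicate_index,
    abundance, is_abundance

Concentrations are ng/mL throughout; abundances are raw ion counts (peak
areas).  ``is_abundance`` is the co-spiked isotope-labeled internal
standard's abundance; when present, the normalized abundance (the
"response ratio") is its quotient with the raw abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("qnta")

IONIZING_GROUPS = (
    "carboxylic_acid",
    "sulfonic_acid",
    "sulfonamide",
    "fluorotelomer_sulfonate",
    "fluoroether",
    "other",
)

CHEMICAL_COLUMNS = [
    "chemical_id",
    "name",
    "retention_time",
    "ionizing_group",
    "chain_length",
    "internal_standard_id",
]

OBSERVATION_COLUMNS = [
    "chemical_id",
    "level_index",
    "true_concentration",
    "replicate_index",
    "abundance",
    "is_abundance",
]


class SchemaError(ValueError):
    """A required column is missing or has an invalid value domain."""


class ReferentialError(ValueError):
    """An observation references a chemical_id with no chemical record."""


class InputError(ValueError):
    """The input file is empty or unreadable as a table."""


class InsufficientDataError(ValueError):
    """Too few rows/points/groups for the requested operation."""


@dataclass(frozen=True)
class ChemicalRecord:
    """Identity and surrogate-selection attributes of one analyte."""

    chemical_id: str
    name: str
    retention_time: float  # minutes
    ionizing_group: str
    chain_length: int  # carbon count
    internal_standard_id: str | None = None

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise SchemaError(
                f"{self.chemical_id}: retention_time must be > 0, "
                f"got {self.retention_time}"
            )
        if self.ionizing_group not in IONIZING_GROUPS:
            raise SchemaError(
                f"{self.chemical_id}: unknown ionizing_group "
                f"{self.ionizing_group!r}"
            )
        if self.chain_length < 1:
            raise SchemaError(
                f"{self.chemical_id}: chain_length must be >= 1"
            )


@dataclass(frozen=True)
class CalibrationObservation:
    """One replicate injection at a known true concentration."""

    chemical_id: str
    level_index: int
    true_concentration: float  # ng/mL
    replicate_index: int
    abundance: float  # ion counts
    is_abundance: float | None = None

    def __post_init__(self) -> None:
        if self.true_concentration <= 0 or self.abundance <= 0:
            raise SchemaError(
                f"{self.chemical_id}: concentration and abundance must be > 0"
            )
        if self.is_abundance is not None and self.is_abundance <= 0:
            raise SchemaError(
                f"{self.chemical_id}: is_abundance must be > 0 when present"
            )

    @property
    def normalized_abundance(self) -> float | None:
        if self.is_abundance is None:
            return None
        return self.abundance / self.is_abundance


@dataclass
class Dataset:
    """A validated collection of chemicals and their calibration injections.

    ``chemicals`` and ``observations`` are pandas DataFrames with the
    column layouts documented in the module docstring; ``observations``
    additionally carries a derived ``normalized_abundance`` column
    (NaN where no internal standard abundance exists).
    """

    chemicals: pd.DataFrame
    observations: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        chem = self.chemicals
        obs = self.observations
        for col in CHEMICAL_COLUMNS:
            if col not in chem.columns:
                raise SchemaError(f"chemicals table missing column {col!r}")
        for col in OBSERVATION_COLUMNS[:-1]:
            if col not in obs.columns:
                raise SchemaError(f"observations table missing column {col!r}")
        if chem["chemical_id"].duplicated().any():
            dup = chem.loc[chem["chemical_id"].duplicated(), "chemical_id"]
            raise SchemaError(f"duplicate chemical_id(s): {sorted(set(dup))}")
        unknown = set(obs["chemical_id"]) - set(chem["chemical_id"])
        if unknown:
            raise ReferentialError(
                f"observations reference unknown chemical_id(s): {sorted(unknown)}"
            )
        if (obs["true_concentration"] <= 0).any() or (obs["abundance"] <= 0).any():
            raise SchemaError("non-positive concentration or abundance")
        if "is_abundance" not in obs.columns:
            obs["is_abundance"] = np.nan
        norm = obs["abundance"] / obs["is_abundance"]
        obs["normalized_abundance"] = norm

    @property
    def chemical_ids(self) -> list[str]:
        return list(self.chemicals["chemical_id"])

    @property
    def n_chemicals(self) -> int:
        return len(self.chemicals)

    def chemical_records(self) -> list[ChemicalRecord]:
        out = []
        for row in self.chemicals.itertuples(index=False):
            is_id = row.internal_standard_id
            if is_id is None or (isinstance(is_id, float) and np.isnan(is_id)):
                is_id = None
            out.append(
                ChemicalRecord(
                    chemical_id=str(row.chemical_id),
                    name=str(row.name),
                    retention_time=float(row.retention_time),
                    ionizing_group=str(row.ionizing_group),
                    chain_length=int(row.chain_length),
                    internal_standard_id=is_id,
                )
            )
        return out

    def observations_for(self, chemical_id: str) -> pd.DataFrame:
        return self.observations[self.observations["chemical_id"] == chemical_id]


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty file") from exc
    if df.empty:
        raise InputError(f"{path}: no data rows")
    return df


def read_dataset(
    calibration_path: str | Path,
    chemicals_path: str | Path,
    label: str = "",
    column_map: Mapping[str, str] | None = None,
) -> Dataset:
    """Read and validate a dataset from its two CSV tables.

    ``column_map`` renames source columns onto the canonical schema
    (``{"source name": "canonical name"}``), which is how externally
    formatted tables (e.g. a study's supplementary files) are ingested.
    Rows with non-positive abundance or concentration are rejected with a
    logged count; rejected + accepted always equals the input row count.
    """
    chem = _read_csv(chemicals_path)
    obs = _read_csv(calibration_path)
    if column_map:
        chem = chem.rename(columns=dict(column_map))
        obs = obs.rename(columns=dict(column_map))
    for col in ("chemical_id", "level_index", "true_concentration",
                "replicate_index", "abundance"):
        if col not in obs.columns:
            raise SchemaError(f"{calibration_path}: missing column {col!r}")
    if "internal_standard_id" not in chem.columns:
        chem["internal_standard_id"] = None
    if "is_abundance" not in obs.columns:
        obs["is_abundance"] = np.nan

    n_in = len(obs)
    bad = (
        (obs["true_concentration"] <= 0)
        | (obs["abundance"] <= 0)
        | obs["abundance"].isna()
        | obs["true_concentration"].isna()
    )
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning(
            "read_dataset: rejected %d of %d rows with non-positive or "
            "missing abundance/concentration", n_rejected, n_in,
        )
    obs = obs[~bad].reset_index(drop=True)
    if obs.empty:
        raise InputError(f"{calibration_path}: no valid rows after filtering")
    logger.info(
        "read_dataset: accepted %d rows, rejected %d (of %d input rows)",
        len(obs), n_rejected, n_in,
    )
    return Dataset(chemicals=chem, observations=obs, label=label)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``chemicals.csv`` and ``calibration.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chem_path = out_dir / "chemicals.csv"
    cal_path = out_dir / "calibration.csv"
    write_table(dataset.chemicals[CHEMICAL_COLUMNS], chem_path)
    write_table(dataset.observations[OBSERVATION_COLUMNS], cal_path)
    return cal_path, chem_path


def write_table(records, path: str | Path) -> None:
    """Write any tabular result to CSV with stable column order.

    Floats are written at 12 significant digits so a round-trip through
    CSV reproduces values to that precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise InputError("write_table: no records to write")
        if hasattr(records[0], "__dataclass_fields__"):
            df = pd.DataFrame([r.__dict__ for r in records])
        else:
            df = pd.DataFrame(records)
    if df.empty:
        raise InputError("write_table: no records to write")
    df.to_csv(path, index=False, float_format="%.12g")
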