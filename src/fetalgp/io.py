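"""Cohort CSV I/O with row-level validation.

The cohort file has one row per pregnancy; the column dictionary is shipped
in ``docs/cohort_schema.md``.  Reading collects row-level validation errors
with line numbers and reports accepted/rejected counts; unknown columns are
warned about and carried through untouched; missing mandatory columns are a
hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .curves import GestationalAge
from .metrics import BiometryScan, DopplerScan

__all__ = [
    "MANDATORY_COLUMNS",
    "OPTIONAL_COLUMNS",
    "PregnancyRecord",
    "CohortReadReport",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "records",
]

MANDATORY_COLUMNS = (
    "subject_id",
    "ifc",
    "maternal_age",
    "maternal_height_cm",
    "maternal_weight_kg",
    "parity",
    "smoking",
    "male_sex",
    "ga20_weeks",
    "efw20_g",
    "ga3t_weeks",
    "efw3t_g",
    "ua_pi",
    "mca_pi",
    "induction",
    "interval_days",
    "ga_delivery_weeks",
    "birthweight_g",
)

OPTIONAL_COLUMNS = (
    "bmi",
    "nulliparity",
    "apgar5",
    "cord_ph",
    "neonatal_ward",
)


class CohortValidationError(ValueError):
    """Hard structural failure of a cohort file (e.g. missing mandatory columns)."""


@dataclass(frozen=True)
class PregnancyRecord:
    """Typed view of one cohort row."""

    subject_id: int
    maternal_age: float
    maternal_height_cm: float
    maternal_weight_kg: float
    bmi: float | None
    parity: int
    smoking: bool
    fetal_sex: str  # "male" | "female"
    scan20: BiometryScan
    scan3t: BiometryScan
    doppler3t: DopplerScan
    ga_delivery: GestationalAge
    interval_days: int
    onset: str  # "induction" | "spontaneous"
    ifc: bool
    birthweight_g: float
    apgar5: int | None = None
    cord_ph: float | None = None
    neonatal_ward: bool | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.interval_days <= 14:
            raise ValueError(
                f"subject {self.subject_id}: interval_days={self.interval_days} violates "
                "the scan-to-delivery window invariant 0 <= interval_days <= 14"
            )
        if float(self.scan3t.ga) > float(self.ga_delivery) + 1e-9:
            raise ValueError(
                f"subject {self.subject_id}: third-trimester scan GA exceeds delivery GA"
            )


@dataclass
class CohortReadReport:
    n_accepted: int = 0
    n_rejected: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)  # (file line number, message)
    warnings: list[str] = field(default_factory=list)


def _validate_row(row: pd.Series) -> list[str]:
    msgs: list[str] = []
    iv = row["interval_days"]
    if not (0 <= iv <= 14):
        msgs.append(
            f"interval_days={iv} violates the invariant 0 <= interval_days <= 14 "
            "(delivery within two weeks of the third-trimester scan)"
        )
    if row["ga3t_weeks"] > row["ga_delivery_weeks"] + 1e-9:
        msgs.append("ga3t_weeks exceeds ga_delivery_weeks")
    for name, lo, hi in (
        ("ga20_weeks", 12.0, 43.0),
        ("ga3t_weeks", 12.0, 43.0),
        ("ga_delivery_weeks", 12.0, 43.0),
    ):
        if not (lo <= row[name] <= hi):
            msgs.append(f"{name}={row[name]} outside [{lo}, {hi}] weeks")
    for name in ("efw20_g", "efw3t_g", "birthweight_g", "maternal_height_cm", "maternal_weight_kg"):
        if not row[name] > 0:
            msgs.append(f"{name}={row[name]} must be positive")
    for name in ("ua_pi", "mca_pi"):
        if not (0 < row[name] < 5):
            msgs.append(f"{name}={row[name]} outside plausible range (0, 5)")
    for name in ("ifc", "smoking", "male_sex", "induction"):
        if row[name] not in (0, 1):
            msgs.append(f"{name}={row[name]} must be 0/1")
    return msgs


def read_cohort(path) -> tuple[Cohort, CohortReadReport]:
    """Read and validate a cohort CSV; invalid rows are rejected, not fatal."""
    path = Path(path)
    df = pd.read_csv(path)
    report = CohortReadReport()

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path.name}: missing mandatory columns {missing}")
    known = set(MANDATORY_COLUMNS) | set(OPTIONAL_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        report.warnings.append(f"unknown columns carried through unvalidated: {unknown}")

    keep = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        msgs = _validate_row(row)
        if msgs:
            keep[i] = False
            # +2: header line plus 1-based indexing
            report.errors.append((i + 2, "; ".join(msgs)))
    accepted = df[keep].reset_index(drop=True)
    report.n_accepted = int(keep.sum())
    report.n_rejected = int((~keep).sum())
    cohort = Cohort(
        data=accepted,
        provenance={"source": str(path), "n_accepted": report.n_accepted,
                    "n_rejected": report.n_rejected},
    )
    return cohort, report


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort CSV (shortest round-trip float representation)."""
    cohort.data.to_csv(path, index=False, lineterminator="\n")


def records(cohort: Cohort) -> list[PregnancyRecord]:
    """Materialise typed records from the cohort table."""
    out: list[PregnancyRecord] = []
    for _, row in cohort.data.iterrows():
        out.append(
            PregnancyRecord(
                subject_id=int(row["subject_id"]),
                maternal_age=float(row["maternal_age"]),
                maternal_height_cm=float(row["maternal_height_cm"]),
                maternal_weight_kg=float(row["maternal_weight_kg"]),
                bmi=float(row["bmi"]) if "bmi" in row and pd.notna(row.get("bmi")) else None,
                parity=int(row["parity"]),
                smoking=bool(row["smoking"]),
                fetal_sex="male" if row["male_sex"] else "female",
                scan20=BiometryScan(
                    ga=GestationalAge(float(row["ga20_weeks"])), efw_grams=float(row["efw20_g"])
                ),
                scan3t=BiometryScan(
                    ga=GestationalAge(float(row["ga3t_weeks"])), efw_grams=float(row["efw3t_g"])
                ),
                doppler3t=DopplerScan(
                    ga=GestationalAge(float(row["ga3t_weeks"])),
                    ua_pi=float(row["ua_pi"]),
                    mca_pi=float(row["mca_pi"]),
                ),
                ga_delivery=GestationalAge(float(row["ga_delivery_weeks"])),
                interval_days=int(row["interval_days"]),
                onset="induction" if row["induction"] else "spontaneous",
                ifc=bool(row["ifc"]),
                birthweight_g=float(row["birthweight_g"]),
                apgar5=int(row["apgar5"]) if "apgar5" in row and pd.notna(row.get("apgar5")) else None,
                cord_ph=float(row["cord_ph"]) if "cord_ph" in row and pd.notna(row.get("cord_ph")) else None,
                neonatal_ward=bool(row["neonatal_ward"])
                if "neonatal_ward" in row and pd.notna(row.get("neonatal_ward"))
                else None,
            )
        )
    return out
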