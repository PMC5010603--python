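"""Relational data model for the four raw EMR tables.

The pipeline consumes four flat CSV tables — patients, diagnoses, drug
records, and lab results — mirroring the minimal extract a health-system
data warehouse would supply for a laboratory-based drug-safety study.
Dates are ISO-8601 strings on disk and :class:`datetime.date` in memory;
everything is day-resolution.  The upper limit of normal (ULN) is carried
per lab row, so results from sites with different assays can be pooled
without an external reference table.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ANALYTES",
    "SEXES",
    "TABLE_SCHEMAS",
    "DrugSpec",
    "StudyConfig",
    "EMRDataset",
    "SchemaError",
    "RowValidationError",
    "icd9_matches",
    "load_dataset",
    "write_dataset",
    "default_study_config",
]

ANALYTES = ("ALT", "AST", "ALP", "BILI")
SEXES = ("male", "female", "unknown")

TABLE_SCHEMAS: Mapping[str, Sequence[str]] = {
    "patients": ("patient_id", "birth_date", "sex"),
    "diagnoses": ("patient_id", "date", "icd9"),
    "drug_records": ("patient_id", "drug", "date", "days_supply", "kind"),
    "lab_results": ("patient_id", "date", "analyte", "value", "uln"),
}

_DATE_COLUMNS = {
    "patients": ("birth_date",),
    "diagnoses": ("date",),
    "drug_records": ("date",),
    "lab_results": ("date",),
}


class SchemaError(ValueError):
    """A table is missing a required column or is otherwise unreadable."""


class RowValidationError(ValueError):
    """A specific row violates a model invariant.

    Carries the table name and zero-based row index so no malformed row
    is ever silently dropped.
    """

    def __init__(self, table: str, row: int, message: str):
        self.table = table
        self.row = row
        super().__init__(f"{table} row {row}: {message}")


def icd9_matches(code: str, entry: str) -> bool:
    """True when dotted ICD-9 ``code`` falls under code-list ``entry``.

    An entry of ``"570"`` matches ``"570"`` itself and every dotted child
    (``"570.1"``) but not ``"5701"``; a dotted entry like ``"189.0"``
    matches itself and fifth-digit children (``"189.01"``).
    """
    if code == entry:
        return True
    if "." in entry:
        return code.startswith(entry)
    return code.startswith(entry + ".")


@dataclass(frozen=True)
class DrugSpec:
    """Study-drug configuration: class membership and exposure imputation."""

    name: str
    anti_vegf: bool = True
    imputed_duration_days: int = 30
    record_kind: str = "prescription"

    def __post_init__(self) -> None:
        if self.imputed_duration_days < 1:
            raise ValueError(f"imputed duration must be positive: {self.name}")


@dataclass
class StudyConfig:
    """Protocol parameters shared by every stage of the analysis."""

    study_drugs: list[DrugSpec]
    accrual_start: datetime.date
    accrual_end: datetime.date
    baseline_window_days: int = 30
    gap_days: int = 30
    dili_extension_days: int = 90
    regimen_window_days: int = 30
    rcc_codes: tuple[str, ...] = ("189.0", "189.1")
    metastasis_code_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "197.0": "lung",
            "197.7": "liver",
            "198.5": "bone_or_marrow",
            "198.3": "brain_or_spinal_cord",
            "198.4": "brain_or_spinal_cord",
            "198.7": "adrenal",
        }
    )
    metastasis_prefixes: tuple[str, ...] = ("196", "197", "198")
    dili_codes: tuple[str, ...] = (
        "277.4",
        "570",
        "572.8",
        "573.3",
        "573.8",
        "576.8",
        "782.4",
    )
    antineoplastic_drugs: tuple[str, ...] = (
        "pazopanib",
        "sorafenib",
        "sunitinib",
        "bevacizumab",
        "interferon",
        "interleukin-2",
        "temsirolimus",
        "everolimus",
        "axitinib",
    )
    year_length_days: float = 365.25
    first_episode_only: bool = False
    hys_law_window_days: int = 0
    alp_required: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accrual_start >= self.accrual_end:
            raise ValueError("accrual_start must precede accrual_end")
        for name in ("baseline_window_days", "gap_days", "dili_extension_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def anti_vegf_drugs(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.study_drugs if d.anti_vegf)

    def drug_spec(self, name: str) -> DrugSpec:
        for spec in self.study_drugs:
            if spec.name == name:
                return spec
        raise KeyError(f"drug not configured: {name}")


def default_study_config(seed: int = 0) -> StudyConfig:
    """The protocol as run: four anti-VEGF drugs, US accrual window.

    Imputed durations are 30 days for pazopanib and sorafenib (oral, no
    days-supply recorded), 28 days for sunitinib (4-weeks-on cycle), and
    14 days per bevacizumab infusion (the indicated dosing interval).
    """
    return StudyConfig(
        study_drugs=[
            DrugSpec("pazopanib", True, 30, "prescription"),
            DrugSpec("sorafenib", True, 30, "prescription"),
            DrugSpec("sunitinib", True, 28, "prescription"),
            DrugSpec("bevacizumab", True, 14, "administration"),
        ],
        accrual_start=datetime.date(2009, 10, 1),
        accrual_end=datetime.date(2013, 2, 17),
        seed=seed,
    )


@dataclass
class EMRDataset:
    """The four raw tables plus a provenance label; the pipeline's sole input.

    Each table is a :class:`pandas.DataFrame` with the documented schema;
    date columns hold :class:`datetime.date` objects.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    drug_records: pd.DataFrame
    lab_results: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        # days_supply is Optional[int]; pandas silently floats it when any
        # value is missing, so pin the column to object None/int.
        if "days_supply" in self.drug_records.columns:
            self.drug_records["days_supply"] = pd.Series(
                [
                    None if v is None or (isinstance(v, float) and pd.isna(v)) else int(v)
                    for v in self.drug_records["days_supply"]
                ],
                index=self.drug_records.index,
                dtype=object,
            )

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def row_counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLE_SCHEMAS}

    def validate(self) -> "EMRDataset":
        """Check every model invariant; raise on the first violation."""
        for name, columns in TABLE_SCHEMAS.items():
            df = self.table(name)
            missing = [c for c in columns if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} missing column(s): {name}.{missing[0]}")

        pat = self.patients
        if pat["patient_id"].duplicated().any():
            dup = int(pat.index[pat["patient_id"].duplicated()][0])
            raise RowValidationError("patients", dup, "duplicate patient_id")
        for i, sex in enumerate(pat["sex"]):
            if sex not in SEXES:
                raise RowValidationError("patients", i, f"invalid sex {sex!r}")

        known = set(pat["patient_id"])
        for name in ("diagnoses", "drug_records", "lab_results"):
            df = self.table(name)
            for i, pid in enumerate(df["patient_id"]):
                if pid not in known:
                    raise RowValidationError(name, i, f"unknown patient_id {pid!r}")

        for i, row in enumerate(self.lab_results.itertuples(index=False)):
            if row.analyte not in ANALYTES:
                raise RowValidationError("lab_results", i, f"invalid analyte {row.analyte!r}")
            if not row.uln > 0:
                raise RowValidationError("lab_results", i, f"non-positive uln {row.uln!r}")
            if row.value < 0:
                raise RowValidationError("lab_results", i, f"negative value {row.value!r}")

        for i, ds in enumerate(self.drug_records["days_supply"]):
            if ds is not None and not pd.isna(ds) and ds < 1:
                raise RowValidationError("drug_records", i, f"days_supply < 1: {ds!r}")
        for i, kind in enumerate(self.drug_records["kind"]):
            if kind not in ("prescription", "administration"):
                raise RowValidationError("drug_records", i, f"invalid kind {kind!r}")

        birth = dict(zip(pat["patient_id"], pat["birth_date"]))
        for name in ("diagnoses", "drug_records", "lab_results"):
            df = self.table(name)
            for i, (pid, d) in enumerate(zip(df["patient_id"], df["date"])):
                if d < birth[pid]:
                    raise RowValidationError(name, i, "record date precedes birth date")
        return self

    def equals(self, other: "EMRDataset") -> bool:
        for name in TABLE_SCHEMAS:
            a = self.table(name).reset_index(drop=True)
            b = other.table(name).reset_index(drop=True)
            if not a.equals(b):
                return False
        return True


def _parse_date(raw: object, table: str, row: int) -> datetime.date:
    try:
        return datetime.date.fromisoformat(str(raw))
    except (TypeError, ValueError):
        raise RowValidationError(table, row, f"unparseable date {raw!r}") from None


def empty_dataset(provenance: str = "empty") -> EMRDataset:
    return EMRDataset(
        patients=pd.DataFrame(columns=list(TABLE_SCHEMAS["patients"])),
        diagnoses=pd.DataFrame(columns=list(TABLE_SCHEMAS["diagnoses"])),
        drug_records=pd.DataFrame(columns=list(TABLE_SCHEMAS["drug_records"])),
        lab_results=pd.DataFrame(columns=list(TABLE_SCHEMAS["lab_results"])),
        provenance=provenance,
    )


def load_dataset(
    paths: Mapping[str, Path | str] | Path | str,
    config: StudyConfig | None = None,
    provenance: str = "loaded",
) -> EMRDataset:
    """Read and validate the four CSV tables.

    ``paths`` is either a directory containing ``patients.csv`` etc., or a
    mapping of table name to file path.  Drug names are normalized to
    lowercase; dates are parsed to calendar dates.  Raises
    :class:`SchemaError` for a missing column and
    :class:`RowValidationError` for a malformed row (with table name and
    row index).
    """
    if not isinstance(paths, Mapping):
        root = Path(paths)
        paths = {name: root / f"{name}.csv" for name in TABLE_SCHEMAS}

    tables: dict[str, pd.DataFrame] = {}
    for name, columns in TABLE_SCHEMAS.items():
        path = Path(paths[name])
        if not path.exists():
            raise SchemaError(f"missing table file: {path}")
        df = pd.read_csv(
            path,
            dtype={"patient_id": str, "icd9": str},
            keep_default_na=False,
            float_precision="round_trip",
        )
        for col in columns:
            if col not in df.columns:
                raise SchemaError(f"missing required column: {name}.{col}")
        df = df[list(columns)]
        for col in _DATE_COLUMNS[name]:
            df[col] = [_parse_date(v, name, i) for i, v in enumerate(df[col])]
        tables[name] = df

    drugs = tables["drug_records"]
    drugs["drug"] = drugs["drug"].astype(str).str.lower()
    supply = []
    for i, v in enumerate(drugs["days_supply"]):
        if v == "" or v is None or (isinstance(v, float) and pd.isna(v)):
            supply.append(None)
        else:
            try:
                supply.append(int(float(v)))
            except (TypeError, ValueError):
                raise RowValidationError(
                    "drug_records", i, f"unparseable days_supply {v!r}"
                ) from None
    drugs["days_supply"] = supply

    labs = tables["lab_results"]
    for col in ("value", "uln"):
        try:
            labs[col] = labs[col].astype(float)
        except ValueError as exc:
            raise SchemaError(f"non-numeric column lab_results.{col}: {exc}") from None

    ds = EMRDataset(provenance=provenance, **tables)
    return ds.validate()


def write_dataset(dataset: EMRDataset, directory: Path | str) -> dict[str, Path]:
    """Write the four tables as UTF-8 CSV; inverse of :func:`load_dataset`."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in TABLE_SCHEMAS:
        df = dataset.table(name).copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = [d.isoformat() for d in df[col]]
        if name == "drug_records":
            df["days_supply"] = ["" if v is None else str(v) for v in df["days_supply"]]
        path = root / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    return written
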