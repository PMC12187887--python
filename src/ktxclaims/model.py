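"""Claims data model: the four-table bundle and its CSV dialect.

A :class:`ClaimsBundle` holds the four raw claims tables as pandas DataFrames
with a fixed schema, plus the :class:`~ktxclaims.config.CodeConfig` governing
their interpretation. The CSV dialect is deliberately rigid — UTF-8, comma
separated, ISO-8601 dates, header row, ``|``-separated code sets — so that a
write/read round trip is exact.

Table schemas
-------------
patients.csv   patient_id, birth_date, sex (male/female/missing), death_date
stays.csv      patient_id, admission_date, discharge_date,
               procedure_codes (|), principal_diagnosis,
               associated_diagnoses (|), is_chemo_delivery (0/1)
deliveries.csv patient_id, delivery_date, atc_code, presentation_id
dialysis.csv   patient_id, session_date
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import CodeConfig, OTHER, default_config

PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "death_date"]
STAY_COLUMNS = [
    "patient_id",
    "admission_date",
    "discharge_date",
    "procedure_codes",
    "principal_diagnosis",
    "associated_diagnoses",
    "is_chemo_delivery",
]
DELIVERY_COLUMNS = ["patient_id", "delivery_date", "atc_code", "presentation_id"]
DIALYSIS_COLUMNS = ["patient_id", "session_date"]

_FILES = {
    "patients": ("patients.csv", PATIENT_COLUMNS),
    "stays": ("stays.csv", STAY_COLUMNS),
    "deliveries": ("deliveries.csv", DELIVERY_COLUMNS),
    "dialysis": ("dialysis.csv", DIALYSIS_COLUMNS),
}

SEX_VALUES = {"male", "female", "missing"}


class BundleValidationError(ValueError):
    """Raised when a bundle violates its invariants.

    ``report`` holds one human-readable line per offending row, each naming
    the file and 1-based data-row number.
    """

    def __init__(self, report: list[str]):
        self.report = list(report)
        preview = "\n".join(self.report[:20])
        more = "" if len(self.report) <= 20 else f"\n... and {len(self.report) - 20} more"
        super().__init__(f"{len(self.report)} validation error(s):\n{preview}{more}")


@dataclass
class ClaimsBundle:
    """The four claims tables plus the code configuration."""

    patients: pd.DataFrame
    stays: pd.DataFrame
    deliveries: pd.DataFrame
    dialysis: pd.DataFrame
    code_config: CodeConfig = field(default_factory=default_config)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @classmethod
    def empty(cls, code_config: CodeConfig | None = None) -> "ClaimsBundle":
        frames = {}
        for name, (_, cols) in _FILES.items():
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            frames[name] = _coerce_dtypes(name, df)
        return cls(code_config=code_config or default_config(), **frames)


def split_codes(cell) -> list[str]:
    """Split a ``|``-separated code cell; empty/NA cells give []."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [c for c in str(cell).split("|") if c]


def join_codes(codes) -> str:
    return "|".join(sorted(set(codes)))


def classify_delivery(atc_code: str, code_config: CodeConfig) -> str:
    """Map a delivery's ATC code to its drug class (``other`` if unmapped)."""
    return code_config.classify_atc(atc_code)


def classify_deliveries(deliveries: pd.DataFrame, code_config: CodeConfig) -> pd.DataFrame:
    """Return a copy of a deliveries table with a ``drug_class`` column."""
    out = deliveries.copy()
    out["drug_class"] = [code_config.classify_atc(a) for a in out["atc_code"]]
    return out


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

_DATE_COLUMNS = {
    "patients": ["birth_date", "death_date"],
    "stays": ["admission_date", "discharge_date"],
    "deliveries": ["delivery_date"],
    "dialysis": ["session_date"],
}
_OPTIONAL_DATES = {("patients", "death_date")}


def _parse_dates(name: str, df: pd.DataFrame, errors: list[str]) -> pd.DataFrame:
    for col in _DATE_COLUMNS[name]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        optional = (name, col) in _OPTIONAL_DATES
        raw = df[col].fillna("").astype(str)
        bad = parsed.isna() & (raw != "")
        if not optional:
            bad |= parsed.isna() & (raw == "")
        for idx in df.index[bad]:
            errors.append(f"{name}.csv row {idx + 1}: unparseable {col} {raw.loc[idx]!r}")
        df[col] = parsed
    return df


def _coerce_dtypes(name: str, df: pd.DataFrame) -> pd.DataFrame:
    for col in _DATE_COLUMNS[name]:
        df[col] = pd.to_datetime(df[col], errors="coerce")
    if name == "stays":
        df["is_chemo_delivery"] = (
            pd.to_numeric(df["is_chemo_delivery"], errors="coerce").fillna(0).astype(int)
        )
        for col in ("procedure_codes", "principal_diagnosis", "associated_diagnoses"):
            df[col] = df[col].fillna("").astype(str)
    if name == "patients":
        df["sex"] = df["sex"].fillna("missing").astype(str)
        df["patient_id"] = df["patient_id"].astype(str)
    if name == "deliveries":
        df["atc_code"] = df["atc_code"].fillna("").astype(str)
        df["presentation_id"] = df["presentation_id"].fillna("").astype(str)
    if "patient_id" in df.columns:
        df["patient_id"] = df["patient_id"].astype(str)
    return df


def validate_bundle(bundle: ClaimsBundle) -> list[str]:
    """Return one line per invariant violation (empty list = valid)."""
    errors: list[str] = []
    patients = bundle.patients
    dup = patients["patient_id"].duplicated(keep=False)
    for idx in patients.index[dup]:
        errors.append(
            f"patients.csv row {idx + 1}: duplicate patient_id {patients.loc[idx, 'patient_id']!r}"
        )
    bad_sex = ~patients["sex"].isin(SEX_VALUES)
    for idx in patients.index[bad_sex]:
        errors.append(f"patients.csv row {idx + 1}: invalid sex {patients.loc[idx, 'sex']!r}")
    has_death = patients["death_date"].notna()
    bad_death = has_death & (patients["death_date"] < patients["birth_date"])
    for idx in patients.index[bad_death]:
        errors.append(f"patients.csv row {idx + 1}: death_date before birth_date")

    stays = bundle.stays
    bad_stay = stays["discharge_date"] < stays["admission_date"]
    for idx in stays.index[bad_stay]:
        errors.append(f"stays.csv row {idx + 1}: discharge_date before admission_date")

    empty_atc = bundle.deliveries["atc_code"].fillna("") == ""
    for idx in bundle.deliveries.index[empty_atc]:
        errors.append(f"deliveries.csv row {idx + 1}: empty atc_code")

    known = set(patients["patient_id"])
    for name in ("stays", "deliveries", "dialysis"):
        table = bundle.table(name)
        orphan = ~table["patient_id"].isin(known)
        for idx in table.index[orphan]:
            errors.append(
                f"{name}.csv row {idx + 1}: unknown patient_id {table.loc[idx, 'patient_id']!r}"
            )
    return errors


def read_bundle(directory_path, code_config: CodeConfig | None = None) -> ClaimsBundle:
    """Read and validate a bundle from a directory of the four CSVs.

    Raises :class:`FileNotFoundError` for a missing table and
    :class:`BundleValidationError` with a line-numbered report when any row
    violates the schema or an invariant.
    """
    directory = Path(directory_path)
    frames: dict[str, pd.DataFrame] = {}
    errors: list[str] = []
    for name, (filename, cols) in _FILES.items():
        path = directory / filename
        if not path.exists():
            raise FileNotFoundError(f"missing required table: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise BundleValidationError(
                [f"{filename}: missing column(s) {', '.join(missing_cols)}"]
            )
        df = df[cols].replace({"": None})
        df = _parse_dates(name, df, errors)
        frames[name] = _coerce_dtypes(name, df)
    bundle = ClaimsBundle(code_config=code_config or default_config(), **frames)
    errors.extend(validate_bundle(bundle))
    if errors:
        raise BundleValidationError(errors)
    return bundle


def _format_dates(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        out[col] = out[col].map(lambda d: "" if pd.isna(d) else pd.Timestamp(d).strftime("%Y-%m-%d"))
    return out


_SORT_KEYS = {
    "patients": ["patient_id"],
    "stays": ["patient_id", "admission_date", "discharge_date"],
    "deliveries": ["patient_id", "delivery_date", "atc_code"],
    "dialysis": ["patient_id", "session_date"],
}


def write_bundle(bundle: ClaimsBundle, directory_path) -> list[Path]:
    """Write the four CSVs with deterministic row order; returns the paths."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, (filename, cols) in _FILES.items():
        df = bundle.table(name)[cols].copy()
        df = df.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(drop=True)
        df = _format_dates(df, _DATE_COLUMNS[name])
        path = directory / filename
        df.to_csv(path, index=False)
        written.append(path)
    return written


def to_date(value) -> datetime.date:
    """Coerce a Timestamp/date to a plain :class:`datetime.date`."""
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, datetime.datetime):
        return value.date()
    return value
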