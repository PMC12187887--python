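"""Code lists, drug-class taxonomy and window parameters shared across the pipeline.

Everything that encodes a coding-system convention (ATC/ICD-10/procedure code
lists) or a temporal rule ("month" = 30 days, "three months" = 91 days) lives
here as plain configuration, so the phenotyping algorithms themselves stay free
of magic numbers and the code lists can be swapped for a real extract's
dictionaries without touching any logic.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

# ---------------------------------------------------------------------------
# Drug classes (molecule level) and therapeutic-group rollups
# ---------------------------------------------------------------------------

TACROLIMUS = "tacrolimus"
CICLOSPORIN = "ciclosporin"
MYCOPHENOLIC_ACID = "mycophenolic_acid"
AZATHIOPRINE = "azathioprine"
EVEROLIMUS = "everolimus"
SIROLIMUS = "sirolimus"
CORTICOSTEROID = "corticosteroid"
BELATACEPT = "belatacept"
OTHER = "other"

#: Every molecule-level class a delivery can be mapped to.
DRUG_CLASSES = (
    TACROLIMUS,
    CICLOSPORIN,
    MYCOPHENOLIC_ACID,
    AZATHIOPRINE,
    EVEROLIMUS,
    SIROLIMUS,
    CORTICOSTEROID,
    BELATACEPT,
    OTHER,
)

#: Therapeutic-group rollups used for regimen recognition and reporting.
CNI = "CNI"
ANTIMETABOLITE = "antimetabolite"
MTORI = "mTORi"

GROUP_OF: dict[str, str] = {
    TACROLIMUS: CNI,
    CICLOSPORIN: CNI,
    MYCOPHENOLIC_ACID: ANTIMETABOLITE,
    AZATHIOPRINE: ANTIMETABOLITE,
    EVEROLIMUS: MTORI,
    SIROLIMUS: MTORI,
    CORTICOSTEROID: CORTICOSTEROID,
    BELATACEPT: BELATACEPT,
    OTHER: OTHER,
}

#: Classes dispensed by community pharmacies (belatacept appears only via the
#: hospital-retrocession channel, emulated from July 2020 onward).
PHARMACY_CLASSES = frozenset(DRUG_CLASSES) - {OTHER}

#: Immunosuppressive classes (everything that counts as "covered" for the
#: treatment-gap graft-loss proxy).
IMMUNOSUPPRESSIVE_CLASSES = frozenset(DRUG_CLASSES) - {OTHER}


def group_of(drug_class: str) -> str:
    """Roll a molecule-level class up to its therapeutic group."""
    return GROUP_OF.get(drug_class, OTHER)


def groups_of(classes: Iterable[str]) -> frozenset[str]:
    return frozenset(group_of(c) for c in classes)


# Default ATC level-5 style map. Pure configuration: every algorithm consults
# the map through CodeConfig, never these literals.
_DEFAULT_DRUG_CLASS_MAP: dict[str, str] = {
    "L04AD02": TACROLIMUS,
    "L04AD01": CICLOSPORIN,
    "L04AA06": MYCOPHENOLIC_ACID,
    "L04AX01": AZATHIOPRINE,
    "L04AA18": EVEROLIMUS,
    "L04AA10": SIROLIMUS,
    "L04AA28": BELATACEPT,
    "H02AB04": CORTICOSTEROID,
    "H02AB06": CORTICOSTEROID,
    "H02AB07": CORTICOSTEROID,
}

# ICD-10-style prefixes (dots stripped, claims style) plus a few ATC prefixes
# for drug-defined conditions; matching is by prefix, mirroring hierarchical
# code families (e.g. E66 covers E660, E669, ...).
_DEFAULT_COMORBIDITY_CODELISTS: dict[str, tuple[str, ...]] = {
    "hypertension": ("I10", "I11", "I12", "I13", "I15", "C09"),
    "dyslipidemia": ("E78", "C10A"),
    "diabetes": ("E10", "E11", "E12", "E13", "E14", "A10"),
    "ischemic_heart_disease": ("I20", "I21", "I22", "I23", "I24", "I25"),
    "obesity_bariatric": ("E66", "HFC"),
    "heart_failure": ("I50",),
    "peripheral_artery_disease": ("I70", "I73"),
    "malnutrition": ("E40", "E41", "E42", "E43", "E44", "E46"),
    "stroke": ("I60", "I61", "I62", "I63", "I64"),
}

#: Recognized multi-class maintenance regimens, expressed at the group level
#: with corticosteroids ignored for recognition.
_DEFAULT_RECOGNIZED_REGIMENS: tuple[frozenset[str], ...] = (
    frozenset({CNI, ANTIMETABOLITE}),
    frozenset({CNI, MTORI}),
    frozenset({MTORI, ANTIMETABOLITE}),
    frozenset({CNI, MTORI, ANTIMETABOLITE}),
    frozenset({BELATACEPT, ANTIMETABOLITE}),
)


@dataclass(frozen=True)
class Windows:
    """Temporal parameters, all in days unless noted.

    The month/three-month conventions are fixed once here: a "month" is 30
    days and "three months" is 91 days, so every rule that the clinical text
    states in months resolves to the same integers everywhere.
    """

    coverage_days: int = 30          # days one pharmacy delivery covers
    merge_gap_days: int = 31         # coverage gaps up to this are bridged
    combination_min_days: int = 30   # minimum simultaneous overlap for a combination
    belatacept_min_stays: int = 3    # infusion-stay count for the proxy algorithm
    belatacept_span_days: int = 90   # window the qualifying stays must fit in
    companion_window_days: int = 90  # mTORi/antimetabolite delivery window
    cni_free_start_day: int = 91     # "fourth month": half-open [91, 121)
    cni_free_end_day: int = 121
    switch_residual_days: int = 30   # old-class coverage >= this => add-on
    initial_regimen_days: int = 90   # window defining the initial regimen
    treatment_gap_days: int = 91     # >91 d without delivery => graft-loss proxy
    dialysis_run_span_days: int = 91     # dialysis run span for the proxy
    dialysis_run_max_gap_days: int = 31  # max inter-session gap within a run
    eligibility_lookback_days: int = 365
    comorbidity_lookback_days: int = 365
    ltfu_silence_days: int = 365     # claim silence implying loss to follow-up
    days_per_year: float = 365.25


@dataclass
class CodeConfig:
    """Code lists and window parameters: the sole source of coding conventions."""

    transplant_procedure_codes: frozenset[str] = frozenset({"JAE003", "HNEA002"})
    other_transplant_procedure_codes: frozenset[str] = frozenset({"DZEA002", "HLEA002"})
    transplant_diagnosis_codes: tuple[str, ...] = ("Z940",)
    drug_class_map: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_DRUG_CLASS_MAP)
    )
    comorbidity_codelists: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_CODELISTS)
    )
    recognized_regimens: tuple[frozenset[str], ...] = _DEFAULT_RECOGNIZED_REGIMENS
    windows: Windows = field(default_factory=Windows)
    study_start: datetime.date = datetime.date(2009, 1, 1)
    study_end: datetime.date = datetime.date(2020, 12, 31)
    history_floor: datetime.date = datetime.date(2008, 1, 1)
    retrocession_start: datetime.date = datetime.date(2020, 7, 1)

    def __post_init__(self) -> None:
        bad = {c for c in self.drug_class_map.values() if c not in DRUG_CLASSES}
        if bad:
            raise ValueError(f"drug_class_map maps to unknown classes: {sorted(bad)}")
        known_groups = set(GROUP_OF.values())
        for regimen in self.recognized_regimens:
            unknown = set(regimen) - known_groups
            if unknown:
                raise ValueError(f"recognized regimen references unknown groups: {sorted(unknown)}")

    # -- lookups -----------------------------------------------------------

    def classify_atc(self, atc_code: str) -> str:
        """Map an ATC code to its drug class; unknown codes map to ``other``."""
        return self.drug_class_map.get(atc_code, OTHER)

    def atc_for_class(self, drug_class: str) -> str:
        """A representative ATC code for a class (used by the simulator)."""
        for atc, cls in self.drug_class_map.items():
            if cls == drug_class:
                return atc
        raise KeyError(drug_class)

    def is_recognized_regimen(self, groups: frozenset[str]) -> bool:
        """Is a non-steroid group set a recognized maintenance regimen?

        Singletons (monotherapy) and the empty/steroid-only set are always
        recognized; multi-group sets must appear in ``recognized_regimens``.
        """
        nonsteroid = frozenset(g for g in groups if g != CORTICOSTEROID)
        if len(nonsteroid) <= 1:
            return True
        return nonsteroid in set(self.recognized_regimens)

    def matches_codelist(self, name: str, codes: Iterable[str]) -> bool:
        """True if any claim code starts with a prefix of the named codelist."""
        try:
            prefixes = self.comorbidity_codelists[name]
        except KeyError:
            raise KeyError(f"unknown comorbidity codelist: {name!r}") from None
        return any(code.startswith(p) for code in codes for p in prefixes)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "transplant_procedure_codes": sorted(self.transplant_procedure_codes),
            "other_transplant_procedure_codes": sorted(self.other_transplant_procedure_codes),
            "transplant_diagnosis_codes": list(self.transplant_diagnosis_codes),
            "drug_class_map": dict(sorted(self.drug_class_map.items())),
            "comorbidity_codelists": {k: list(v) for k, v in sorted(self.comorbidity_codelists.items())},
            "recognized_regimens": sorted("+".join(sorted(r)) for r in self.recognized_regimens),
            "windows": dataclasses.asdict(self.windows),
            "study_start": self.study_start.isoformat(),
            "study_end": self.study_end.isoformat(),
            "history_floor": self.history_floor.isoformat(),
            "retrocession_start": self.retrocession_start.isoformat(),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CodeConfig":
        kwargs: dict = {}
        if "transplant_procedure_codes" in data:
            kwargs["transplant_procedure_codes"] = frozenset(data["transplant_procedure_codes"])
        if "other_transplant_procedure_codes" in data:
            kwargs["other_transplant_procedure_codes"] = frozenset(data["other_transplant_procedure_codes"])
        if "transplant_diagnosis_codes" in data:
            kwargs["transplant_diagnosis_codes"] = tuple(data["transplant_diagnosis_codes"])
        if "drug_class_map" in data:
            kwargs["drug_class_map"] = dict(data["drug_class_map"])
        if "comorbidity_codelists" in data:
            kwargs["comorbidity_codelists"] = {k: tuple(v) for k, v in data["comorbidity_codelists"].items()}
        if "recognized_regimens" in data:
            kwargs["recognized_regimens"] = tuple(
                frozenset(r.split("+")) for r in data["recognized_regimens"]
            )
        if "windows" in data:
            kwargs["windows"] = Windows(**data["windows"])
        for key in ("study_start", "study_end", "history_floor", "retrocession_start"):
            if key in data:
                value = data[key]
                if isinstance(value, str):
                    value = datetime.date.fromisoformat(value)
                kwargs[key] = value
        return cls(**kwargs)

    def save_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "CodeConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_config() -> CodeConfig:
    """A fresh CodeConfig with the package defaults."""
    return CodeConfig()
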