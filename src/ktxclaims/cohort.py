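"""Cohort construction: index transplantations, eligibility, baseline profile.

The index event is the admission date of a patient's first transplant-coded
hospital stay within the study period. Eligibility excludes minors, patients
with undocumented sex, patients absent from the database in the year before
index (zero claims of any type), and records with data inconsistencies (death
before index, or claims after death). Exclusions are attributed to the first
failing rule in that order, so the report partitions the screened patients.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CodeConfig
from .model import ClaimsBundle, split_codes

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("under_18", "missing_sex", "absent_prior_year", "inconsistent")

INDEX_COLUMNS = ["patient_id", "index_date", "age_at_index", "index_year"]


@dataclass
class EligibilityReport:
    """Patient-flow counts; ``screened == eligible + sum(excluded)``."""

    screened: int = 0
    eligible: int = 0
    excluded: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )

    def to_dict(self) -> dict:
        return {"screened": self.screened, "eligible": self.eligible,
                "excluded": dict(self.excluded)}


def _has_transplant_code(cell: str, codes: frozenset[str]) -> bool:
    return any(c in codes for c in split_codes(cell))


def find_index(bundle: ClaimsBundle,
               study_period: tuple[datetime.date, datetime.date] | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Identify index transplantations and later retransplant candidates.

    Returns ``(index_events, retransplants)``. Index events hold, per patient
    with at least one transplant-coded stay in the period, the earliest such
    stay's admission date (ties on the same date collapse to one event).
    ``retransplants`` lists every transplant-coded stay admitted strictly
    after the patient's index date.
    """
    config = bundle.code_config
    if study_period is None:
        study_period = (config.study_start, config.study_end)
    start, end = (pd.Timestamp(study_period[0]), pd.Timestamp(study_period[1]))

    stays = bundle.stays
    is_tx = stays["procedure_codes"].map(
        lambda c: _has_transplant_code(c, config.transplant_procedure_codes))
    tx = stays[is_tx] if len(stays) else stays
    in_period = tx[(tx["admission_date"] >= start) & (tx["admission_date"] <= end)]
    if len(in_period) == 0:
        empty_idx = pd.DataFrame(columns=INDEX_COLUMNS)
        empty_retx = pd.DataFrame(columns=["patient_id", "admission_date"])
        return empty_idx, empty_retx

    idx = (in_period.groupby("patient_id", as_index=False)["admission_date"].min()
           .rename(columns={"admission_date": "index_date"}))
    birth = bundle.patients.set_index("patient_id")["birth_date"]
    idx["age_at_index"] = [
        int(np.floor((row.index_date - birth.get(row.patient_id, pd.NaT)).days / 365.25))
        if pd.notna(birth.get(row.patient_id, pd.NaT)) else -1
        for row in idx.itertuples()
    ]
    idx["index_year"] = idx["index_date"].dt.year
    idx = idx[INDEX_COLUMNS].sort_values("patient_id").reset_index(drop=True)

    index_map = idx.set_index("patient_id")["index_date"]
    later = tx[tx["patient_id"].isin(index_map.index)].copy()
    later = later[later["admission_date"] > later["patient_id"].map(index_map)]
    retransplants = (later[["patient_id", "admission_date"]]
                     .drop_duplicates()
                     .sort_values(["patient_id", "admission_date"])
                     .reset_index(drop=True))
    logger.info("find_index: %d index events, %d retransplant candidates",
                len(idx), len(retransplants))
    return idx, retransplants


def _claim_dates(bundle: ClaimsBundle) -> pd.DataFrame:
    """All claim dates per patient (stay admissions, deliveries, dialysis)."""
    parts = [
        bundle.stays[["patient_id", "admission_date"]].rename(columns={"admission_date": "date"}),
        bundle.deliveries[["patient_id", "delivery_date"]].rename(columns={"delivery_date": "date"}),
        bundle.dialysis[["patient_id", "session_date"]].rename(columns={"session_date": "date"}),
    ]
    return pd.concat(parts, ignore_index=True)


def apply_eligibility(index_events: pd.DataFrame, bundle: ClaimsBundle
                      ) -> tuple[pd.DataFrame, EligibilityReport]:
    """Apply the exclusion rules; returns the cohort and the flow report."""
    config = bundle.code_config
    lookback = config.windows.eligibility_lookback_days
    patients = bundle.patients.set_index("patient_id")
    claims = _claim_dates(bundle)
    claims_by_patient = dict(tuple(claims.groupby("patient_id")["date"]))

    report = EligibilityReport(screened=len(index_events))
    keep_rows = []
    for row in index_events.itertuples():
        pid, index_date = row.patient_id, row.index_date
        sex = patients.loc[pid, "sex"]
        death = patients.loc[pid, "death_date"]
        dates = claims_by_patient.get(pid)

        reason = None
        if row.age_at_index < 18:
            reason = "under_18"
        elif sex == "missing":
            reason = "missing_sex"
        else:
            window_lo = index_date - pd.Timedelta(days=lookback)
            present = dates is not None and bool(
                ((dates >= window_lo) & (dates < index_date)).any())
            if not present:
                reason = "absent_prior_year"
            elif pd.notna(death) and (
                    death < index_date or bool((dates > death).any())):
                reason = "inconsistent"
        if reason is None:
            report.eligible += 1
            keep_rows.append(row.Index)
        else:
            report.excluded[reason] += 1
    cohort = index_events.loc[keep_rows].reset_index(drop=True)
    logger.info("apply_eligibility: %d screened -> %d eligible (%s)",
                report.screened, report.eligible, report.excluded)
    return cohort, report


BASELINE_HISTORY_FLAGS = (
    "multiple_transplantation",
    "prior_kidney_transplant",
    "prior_other_transplant",
    "preemptive",
)


def flag_baseline(cohort: pd.DataFrame, bundle: ClaimsBundle,
                  config: CodeConfig | None = None) -> pd.DataFrame:
    """Comorbidity and transplant-history flags from pre-index claims only.

    Comorbidities scan stay diagnoses, stay procedures and delivery ATC codes
    in the year before index (prefix match against the configured codelists).
    Transplant-history flags use the full historical window back to the
    configured floor; pre-emptive means no dialysis session before index.
    """
    config = config or bundle.code_config
    lookback = config.windows.comorbidity_lookback_days
    floor = pd.Timestamp(config.history_floor)
    conditions = sorted(config.comorbidity_codelists)

    stays_by_patient = dict(tuple(bundle.stays.groupby("patient_id")))
    deliv_by_patient = dict(tuple(bundle.deliveries.groupby("patient_id")))
    dial_by_patient = dict(tuple(bundle.dialysis.groupby("patient_id")["session_date"]))

    rows = []
    for row in cohort.itertuples():
        pid, index_date = row.patient_id, row.index_date
        lo = index_date - pd.Timedelta(days=lookback)

        codes: list[str] = []
        stays = stays_by_patient.get(pid)
        tx_before = other_tx_before = False
        multi = False
        if stays is not None:
            recent = stays[(stays["admission_date"] >= lo) & (stays["admission_date"] < index_date)]
            for stay in recent.itertuples():
                codes.extend(split_codes(stay.procedure_codes))
                codes.extend(split_codes(stay.principal_diagnosis))
                codes.extend(split_codes(stay.associated_diagnoses))
            history = stays[(stays["admission_date"] >= floor) & (stays["admission_date"] < index_date)]
            for stay in history.itertuples():
                procs = set(split_codes(stay.procedure_codes))
                if procs & config.transplant_procedure_codes:
                    tx_before = True
                if procs & config.other_transplant_procedure_codes:
                    other_tx_before = True
            index_stays = stays[stays["admission_date"] == index_date]
            for stay in index_stays.itertuples():
                if set(split_codes(stay.procedure_codes)) & config.other_transplant_procedure_codes:
                    multi = True
        deliv = deliv_by_patient.get(pid)
        if deliv is not None:
            recent_d = deliv[(deliv["delivery_date"] >= lo) & (deliv["delivery_date"] < index_date)]
            codes.extend(recent_d["atc_code"].tolist())

        sessions = dial_by_patient.get(pid)
        preemptive = sessions is None or not bool((sessions < index_date).any())

        flags = {c: config.matches_codelist(c, codes) for c in conditions}
        rows.append({"patient_id": pid, **flags,
                     "multiple_transplantation": multi,
                     "prior_kidney_transplant": tx_before,
                     "prior_other_transplant": other_tx_before,
                     "preemptive": preemptive})
    columns = ["patient_id", *conditions, *BASELINE_HISTORY_FLAGS]
    return pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
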