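"""Graft-loss proxy and competing-risk outcome assembly.

Graft failure is not coded as such in claims; it is dated by the earliest of
three proxies: (a) the end of all immunosuppressive coverage followed by more
than three months (91 days) with no delivery, dated at the coverage end;
(b) a retransplantation stay, dated at its admission; (c) a sustained
dialysis resumption — a run of post-index sessions spanning at least 91 days
with no inter-session gap above 31 days — dated at the run's first session.
Gaps truncated by death or the end of the study do not qualify.

Outcome codes: 0 = censored, 1 = graft loss, 2 = death. Graft loss strictly
before death wins; a same-day tie is coded as death, since terminal
hospitalizations would otherwise masquerade as graft failures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CodeConfig, IMMUNOSUPPRESSIVE_CLASSES
from .exposure import ExposureTimeline, union_intervals
from .model import ClaimsBundle

logger = logging.getLogger(__name__)

CENSORED, GRAFT_LOSS, DEATH = 0, 1, 2

OUTCOME_COLUMNS = ["patient_id", "time_years", "event_code",
                   "graft_loss_reason", "censor_reason"]


@dataclass
class GraftLossCall:
    day: int | None
    reason: str  # "treatment_gap" | "retransplant" | "dialysis_resumption" | "none"


def detect_graft_loss(timeline: ExposureTimeline,
                      retransplant_days: np.ndarray,
                      dialysis_days: np.ndarray,
                      observation_end_day: int,
                      code_config: CodeConfig) -> GraftLossCall:
    """Date graft loss for one patient via the three-proxy rule.

    ``observation_end_day`` is min(death, study end) in days from index; a
    treatment gap must fit entirely before it to qualify.
    """
    w = code_config.windows
    candidates: list[tuple[int, str]] = []

    # (a) treatment gap after the end of all-class coverage
    covered = union_intervals([
        iv for cls, ivs in timeline.intervals.items()
        if cls in IMMUNOSUPPRESSIVE_CLASSES for iv in ivs])
    delivery_starts = sorted(a for a, _ in covered)
    for i, (_, end) in enumerate(covered):
        nxt = next((s for s in delivery_starts if s > end), None)
        gap_end = nxt if nxt is not None else observation_end_day
        if gap_end - end > w.treatment_gap_days:
            candidates.append((end, "treatment_gap"))
            break

    # (b) retransplantation
    retx = np.asarray(retransplant_days, dtype=int)
    if len(retx):
        candidates.append((int(retx.min()), "retransplant"))

    # (c) sustained dialysis resumption
    days = np.unique(np.asarray(dialysis_days, dtype=int))
    days = days[days > 0]
    if len(days):
        breaks = np.nonzero(np.diff(days) > w.dialysis_run_max_gap_days)[0]
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [len(days) - 1]])
        for s, e in zip(run_starts, run_ends):
            if days[e] - days[s] >= w.dialysis_run_span_days:
                candidates.append((int(days[s]), "dialysis_resumption"))
                break

    if not candidates:
        return GraftLossCall(None, "none")
    day, reason = min(candidates, key=lambda c: c[0])
    return GraftLossCall(day, reason)


def assemble_outcomes(cohort: pd.DataFrame,
                      graft_losses: dict[str, GraftLossCall],
                      bundle: ClaimsBundle,
                      last_claim_days: dict[str, int] | None = None
                      ) -> pd.DataFrame:
    """One outcome record per cohort member.

    Event time is the first of graft loss, death, and censoring. Censoring is
    at the end of the study, or — when the patient's claims fall silent for
    more than a year before study end without a recorded death — at the last
    claim (lost to follow-up).
    """
    config = bundle.code_config
    w = config.windows
    study_end = pd.Timestamp(config.study_end)
    dpy = w.days_per_year
    patients = bundle.patients.set_index("patient_id")
    if last_claim_days is None:
        last_claim_days = compute_last_claim_days(bundle, cohort)

    rows = []
    for row in cohort.itertuples():
        pid, index_date = row.patient_id, row.index_date
        end_day = (study_end - index_date).days
        death = patients.loc[pid, "death_date"]
        death_day = (death - index_date).days if pd.notna(death) else None
        if death_day is not None and death_day > end_day:
            death_day = None

        last_claim = last_claim_days.get(pid)
        censor_day, censor_reason = end_day, "study_end"
        if death_day is None and last_claim is not None \
                and end_day - last_claim > w.ltfu_silence_days:
            censor_day, censor_reason = max(last_claim, 0), "lost_to_followup"

        call = graft_losses.get(pid, GraftLossCall(None, "none"))
        gl_day = call.day

        t = censor_day
        code = CENSORED
        gl_reason = "none"
        if death_day is not None and death_day <= t:
            t, code, censor_reason = death_day, DEATH, "none"
        if gl_day is not None and gl_day < t or (
                gl_day is not None and gl_day == t and code == CENSORED):
            t, code, gl_reason, censor_reason = gl_day, GRAFT_LOSS, call.reason, "none"
        if code != CENSORED:
            censor_reason = "none"
        rows.append((pid, max(t, 0) / dpy, code, gl_reason, censor_reason))

    out = pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
    logger.info("assemble_outcomes: %d records (%d graft losses, %d deaths)",
                len(out), int((out.event_code == GRAFT_LOSS).sum()),
                int((out.event_code == DEATH).sum()))
    return out


def compute_last_claim_days(bundle: ClaimsBundle, cohort: pd.DataFrame
                            ) -> dict[str, int]:
    """Day offset of each cohort member's latest claim of any type."""
    parts = [
        bundle.stays[["patient_id", "admission_date"]].rename(columns={"admission_date": "date"}),
        bundle.deliveries[["patient_id", "delivery_date"]].rename(columns={"delivery_date": "date"}),
        bundle.dialysis[["patient_id", "session_date"]].rename(columns={"session_date": "date"}),
    ]
    claims = pd.concat(parts, ignore_index=True)
    last = claims.groupby("patient_id")["date"].max()
    out: dict[str, int] = {}
    for row in cohort.itertuples():
        if row.patient_id in last.index:
            out[row.patient_id] = int((last[row.patient_id] - row.index_date).days)
    return out


def compute_outcomes(bundle: ClaimsBundle, cohort: pd.DataFrame,
                     timelines: dict[str, ExposureTimeline],
                     retransplants: pd.DataFrame) -> pd.DataFrame:
    """Bundle-level driver: graft-loss detection then outcome assembly."""
    config = bundle.code_config
    study_end = pd.Timestamp(config.study_end)
    patients = bundle.patients.set_index("patient_id")
    retx_by_patient = {pid: grp for pid, grp in retransplants.groupby("patient_id")} \
        if len(retransplants) else {}
    dial_by_patient = dict(tuple(bundle.dialysis.groupby("patient_id")["session_date"]))

    calls: dict[str, GraftLossCall] = {}
    for row in cohort.itertuples():
        pid, index_date = row.patient_id, row.index_date
        end_day = (study_end - index_date).days
        death = patients.loc[pid, "death_date"]
        if pd.notna(death):
            end_day = min(end_day, (death - index_date).days)
        retx_days = np.array([], dtype=int)
        if pid in retx_by_patient:
            retx_days = ((retx_by_patient[pid]["admission_date"] - index_date)
                         .dt.days.to_numpy())
        dial_days = np.array([], dtype=int)
        if pid in dial_by_patient:
            dial_days = (dial_by_patient[pid] - index_date).dt.days.to_numpy()
        tl = timelines.get(pid, ExposureTimeline(pid))
        calls[pid] = detect_graft_loss(tl, retx_days, dial_days, end_day, config)

    return assemble_outcomes(cohort, calls, bundle)
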