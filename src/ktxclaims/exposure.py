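"""Drug-exposure timelines and the rule-based phenotyping algorithms.

All times here are integer day offsets from the patient's index date, with
half-open intervals ``[start, end)``. A pharmacy delivery covers
``coverage_days`` (default 30) from its date; per-class coverage intervals are
merged when the gap between consecutive covers is at most ``merge_gap_days``
(default 31), i.e. one skipped refill does not break an episode.

Three phenotyping rules live here:

* combination detection — a multi-class regimen counts as a combination only
  when the simultaneous overlap lasts at least 30 days and the non-steroid
  class set is a recognized maintenance regimen; shorter overlaps are treated
  as transition slack and attributed to the preceding period;
* belatacept identification — belatacept is infused in hospital and invisible
  in community-pharmacy claims, so patients are identified by a three-clause
  proxy: (1) at least three chemotherapy-delivery stays carrying a kidney-
  transplant diagnosis within a 90-day span, (2) at least one mTOR-inhibitor
  or antimetabolite delivery within 90 days of the index hospitalization, and
  (3) no CNI delivery during the fourth month (days 91-120) after it; a
  belatacept-coded pharmacy delivery (hospital retrocession) short-circuits
  the algorithm;
* switch / add-on detection — the regimen in place is deemed stopped on the
  date of first delivery of a relay class; if the previous classes' coverage
  continues for at least 30 days alongside the new class, the event is an
  add-on instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CodeConfig, CORTICOSTEROID, BELATACEPT, ANTIMETABOLITE, MTORI, CNI, group_of, groups_of
from .model import ClaimsBundle, classify_deliveries, split_codes

logger = logging.getLogger(__name__)


@dataclass
class ExposureTimeline:
    """Per-class coverage intervals (days from index, half-open, disjoint)."""

    patient_id: str
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def classes(self) -> frozenset[str]:
        return frozenset(self.intervals)

    def covered_at(self, drug_class: str, day: int) -> bool:
        return any(a <= day < b for a, b in self.intervals.get(drug_class, []))

    def interval_containing(self, drug_class: str, day: int) -> tuple[int, int] | None:
        for a, b in self.intervals.get(drug_class, []):
            if a <= day < b:
                return (a, b)
        return None

    def first_start(self, drug_class: str) -> int | None:
        ivs = self.intervals.get(drug_class)
        return ivs[0][0] if ivs else None


@dataclass
class RegimenPeriod:
    start: int
    end: int
    classes: frozenset[str]
    recognized: bool

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class SwitchEvent:
    patient_id: str
    day: int
    from_classes: frozenset[str]
    to_classes: frozenset[str]
    kind: str  # "switch" | "add_on"


@dataclass
class BelataceptCall:
    patient_id: str
    positive: bool
    index_hospitalization_day: int | None
    three_stays_90d: bool
    companion_delivery_90d: bool
    no_cni_fourth_month: bool
    source: str  # "algorithm" | "direct_retrocession" | "none"


# ---------------------------------------------------------------------------
# Coverage timelines
# ---------------------------------------------------------------------------

def merge_covers(days: np.ndarray, coverage_days: int, merge_gap_days: int
                 ) -> list[tuple[int, int]]:
    """Merge per-delivery covers ``[d, d+coverage)`` bridging gaps <= merge_gap."""
    if len(days) == 0:
        return []
    days = np.unique(np.asarray(days, dtype=int))
    out: list[tuple[int, int]] = []
    start = int(days[0])
    end = int(days[0]) + coverage_days
    for d in days[1:]:
        d = int(d)
        if d - end <= merge_gap_days:
            end = max(end, d + coverage_days)
        else:
            out.append((start, end))
            start, end = d, d + coverage_days
    out.append((start, end))
    return out


def build_timeline(deliveries_for_patient: pd.DataFrame, code_config: CodeConfig,
                   patient_id: str = "") -> ExposureTimeline:
    """Build a coverage timeline from one patient's classified deliveries.

    ``deliveries_for_patient`` needs columns ``day`` (int offset from index)
    and ``drug_class``. Deliveries classified ``other`` are ignored.
    """
    w = code_config.windows
    intervals: dict[str, list[tuple[int, int]]] = {}
    if len(deliveries_for_patient):
        for drug_class, grp in deliveries_for_patient.groupby("drug_class"):
            if drug_class == "other":
                continue
            intervals[drug_class] = merge_covers(
                grp["day"].to_numpy(), w.coverage_days, w.merge_gap_days)
    return ExposureTimeline(patient_id=patient_id, intervals=intervals)


def _group_intervals(timeline: ExposureTimeline) -> dict[str, list[tuple[int, int]]]:
    """Union per-class intervals up to therapeutic groups."""
    grouped: dict[str, list[tuple[int, int]]] = {}
    for drug_class, ivs in timeline.intervals.items():
        grouped.setdefault(group_of(drug_class), []).extend(ivs)
    return {g: union_intervals(ivs) for g, ivs in grouped.items()}


def union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (overlapping or abutting are merged)."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


# ---------------------------------------------------------------------------
# Combination periods
# ---------------------------------------------------------------------------

def detect_combinations(timeline: ExposureTimeline, code_config: CodeConfig
                        ) -> list[RegimenPeriod]:
    """Partition covered follow-up into maximal constant-group periods.

    Multi-group periods (ignoring corticosteroids) shorter than the 30-day
    combination threshold are transition slack: their days are attributed to
    the preceding period (or, at the very start, to the following one).
    """
    w = code_config.windows
    grouped = _group_intervals(timeline)
    if not grouped:
        return []
    bounds = sorted({x for ivs in grouped.values() for ab in ivs for x in ab})
    raw: list[RegimenPeriod] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        active = frozenset(
            g for g, ivs in grouped.items() if any(s <= a and b <= e for s, e in ivs))
        if not active:
            continue
        if raw and raw[-1].classes == active and raw[-1].end == a:
            raw[-1].end = b
        else:
            raw.append(RegimenPeriod(a, b, active, True))

    # fold sub-threshold multi-group periods into their neighbor
    changed = True
    while changed:
        changed = False
        for i, p in enumerate(raw):
            nonsteroid = {g for g in p.classes if g != CORTICOSTEROID}
            if len(nonsteroid) >= 2 and p.duration < w.combination_min_days:
                if i > 0 and raw[i - 1].end == p.start:
                    raw[i - 1].end = p.end
                elif i + 1 < len(raw) and raw[i + 1].start == p.end:
                    raw[i + 1].start = p.start
                else:
                    continue
                del raw[i]
                changed = True
                break
        # re-merge equal contiguous neighbors
        i = 0
        while i + 1 < len(raw):
            if raw[i].classes == raw[i + 1].classes and raw[i].end == raw[i + 1].start:
                raw[i].end = raw[i + 1].end
                del raw[i + 1]
                changed = True
            else:
                i += 1

    for p in raw:
        p.recognized = code_config.is_recognized_regimen(p.classes)
    return raw


# ---------------------------------------------------------------------------
# Belatacept identification
# ---------------------------------------------------------------------------

def qualifying_stay_days(stays_for_patient: pd.DataFrame, code_config: CodeConfig
                         ) -> np.ndarray:
    """Admission days of chemo-delivery stays carrying a transplant diagnosis."""
    if not len(stays_for_patient):
        return np.array([], dtype=int)
    prefixes = tuple(code_config.transplant_diagnosis_codes)

    def is_qualifying(row) -> bool:
        if not row.is_chemo_delivery:
            return False
        codes = split_codes(row.principal_diagnosis) + split_codes(row.associated_diagnoses)
        return any(c.startswith(p) for c in codes for p in prefixes)

    days = [row.day for row in stays_for_patient.itertuples() if is_qualifying(row)]
    return np.sort(np.asarray(days, dtype=int))


def detect_belatacept(stays_for_patient: pd.DataFrame,
                      deliveries_for_patient: pd.DataFrame,
                      code_config: CodeConfig,
                      patient_id: str = "") -> BelataceptCall:
    """Apply the three-clause belatacept proxy algorithm to one patient.

    ``stays_for_patient`` needs ``day``, ``is_chemo_delivery``,
    ``principal_diagnosis``, ``associated_diagnoses``; ``deliveries_for_patient``
    needs ``day`` and ``drug_class``. Day offsets are from the transplant
    index date; windows are anchored at the index hospitalization (the
    earliest stay of the earliest qualifying three-stay window).
    """
    w = code_config.windows
    k = w.belatacept_min_stays
    days = qualifying_stay_days(stays_for_patient, code_config)

    index_hosp: int | None = None
    if len(days) >= k:
        spans = days[k - 1:] - days[: len(days) - k + 1]
        hits = np.nonzero(spans <= w.belatacept_span_days)[0]
        if len(hits):
            index_hosp = int(days[hits[0]])
    three_stays = index_hosp is not None

    if len(deliveries_for_patient):
        d_days = deliveries_for_patient["day"].to_numpy()
        d_cls = deliveries_for_patient["drug_class"].to_numpy()
    else:
        d_days = np.array([], dtype=int)
        d_cls = np.array([], dtype=object)

    direct = bool((d_cls == BELATACEPT).any())

    companion = no_cni = False
    if three_stays:
        groups = np.array([group_of(c) for c in d_cls]) if len(d_cls) else np.array([])
        in_window = (d_days >= index_hosp) & (d_days <= index_hosp + w.companion_window_days)
        companion = bool(len(d_cls) and np.any(in_window & np.isin(groups, (MTORI, ANTIMETABOLITE))))
        fourth_month = (d_days >= index_hosp + w.cni_free_start_day) & (
            d_days < index_hosp + w.cni_free_end_day)
        no_cni = not bool(len(d_cls) and np.any(fourth_month & (groups == CNI)))

    algorithm_positive = three_stays and companion and no_cni
    positive = algorithm_positive or direct
    source = "direct_retrocession" if direct else ("algorithm" if algorithm_positive else "none")
    return BelataceptCall(
        patient_id=patient_id,
        positive=positive,
        index_hospitalization_day=index_hosp,
        three_stays_90d=three_stays,
        companion_delivery_90d=companion,
        no_cni_fourth_month=no_cni,
        source=source,
    )


# ---------------------------------------------------------------------------
# Switches / add-ons
# ---------------------------------------------------------------------------

def detect_switches(timeline: ExposureTimeline, code_config: CodeConfig,
                    belatacept_call: "BelataceptCall | None" = None
                    ) -> list[SwitchEvent]:
    """Relay-treatment events, in chronological order.

    A class whose first coverage starts more than ``coverage_days`` after the
    earliest covered day is a relay arrival. At the arrival day ``t`` of class
    ``c``: classes still covered at ``t`` whose current coverage interval ends
    before ``t + 30`` are stopping (their last delivery precedes the relay);
    if any class stops the event is a switch, otherwise an add-on.
    Corticosteroids neither trigger nor join events.

    When a positive belatacept call is supplied, the belatacept class is
    anchored at the call's index hospitalization: hospital infusions predate
    any community (retrocession) delivery, so the first pharmacy-visible
    belatacept delivery is a reporting artifact, not a therapy change.
    """
    w = code_config.windows
    starts = {c: ivs[0][0] for c, ivs in timeline.intervals.items()
              if ivs and c != CORTICOSTEROID}
    if (belatacept_call is not None and belatacept_call.positive
            and belatacept_call.index_hospitalization_day is not None
            and BELATACEPT in starts):
        starts[BELATACEPT] = min(starts[BELATACEPT],
                                 belatacept_call.index_hospitalization_day)
    if not starts:
        return []
    t0 = min(starts.values())
    arrivals = sorted(
        (t, c) for c, t in starts.items() if t >= t0 + w.coverage_days)

    events: list[SwitchEvent] = []
    for t, c in arrivals:
        active = set()
        stopped = set()
        for a in timeline.intervals:
            if a == c or a == CORTICOSTEROID:
                continue
            iv = timeline.interval_containing(a, t)
            if iv is None:
                # coverage ending exactly on the relay day still counts as
                # the treatment being replaced
                iv = timeline.interval_containing(a, t - 1)
            if iv is None:
                continue
            active.add(a)
            if iv[1] < t + w.switch_residual_days:
                stopped.add(a)
        if not active:
            # resumption after a coverage gap: treat as a switch from the
            # most recent covered set before t
            prior = frozenset(
                a for a in timeline.intervals
                if a != c and a != CORTICOSTEROID and
                any(b <= t for _, b in timeline.intervals[a]))
            events.append(SwitchEvent(timeline.patient_id, t, prior, frozenset({c}), "switch"))
            continue
        if stopped:
            events.append(SwitchEvent(
                timeline.patient_id, t, frozenset(active),
                frozenset((active - stopped) | {c}), "switch"))
        else:
            events.append(SwitchEvent(
                timeline.patient_id, t, frozenset(active),
                frozenset(active | {c}), "add_on"))
    return events


def initial_regimen(timeline: ExposureTimeline, belatacept_call: BelataceptCall | None,
                    code_config: CodeConfig) -> frozenset[str]:
    """Therapeutic groups covered within the first 90 days post index.

    A positive belatacept call whose index hospitalization falls in that
    window contributes the belatacept group. An empty set means no documented
    community-pharmacy immunosuppression (e.g. entirely hospital-delivered).
    """
    w = code_config.windows
    horizon = w.initial_regimen_days
    groups = set()
    for drug_class, ivs in timeline.intervals.items():
        if any(a < horizon and b > 0 for a, b in ivs):
            groups.add(group_of(drug_class))
    if belatacept_call is not None and belatacept_call.positive:
        h = belatacept_call.index_hospitalization_day
        if h is None or h <= horizon:
            groups.add(BELATACEPT)
    groups.discard("other")
    return frozenset(groups)


# ---------------------------------------------------------------------------
# Bundle-level driver
# ---------------------------------------------------------------------------

@dataclass
class ExposureResult:
    timelines: dict[str, ExposureTimeline]
    regimen_periods: dict[str, list[RegimenPeriod]]
    switches: dict[str, list[SwitchEvent]]
    belatacept_calls: dict[str, BelataceptCall]
    initial_regimens: dict[str, frozenset[str]]

    def timelines_frame(self) -> pd.DataFrame:
        rows = [(pid, c, a, b)
                for pid, tl in sorted(self.timelines.items())
                for c in sorted(tl.intervals)
                for a, b in tl.intervals[c]]
        return pd.DataFrame(rows, columns=["patient_id", "drug_class", "start_day", "end_day"])

    def switches_frame(self) -> pd.DataFrame:
        rows = [(pid, e.day, "|".join(sorted(e.from_classes)),
                 "|".join(sorted(e.to_classes)), e.kind)
                for pid, evs in sorted(self.switches.items()) for e in evs]
        return pd.DataFrame(rows, columns=["patient_id", "day", "from_classes", "to_classes", "kind"])

    def belatacept_frame(self) -> pd.DataFrame:
        rows = [(pid, c.positive, c.index_hospitalization_day, c.three_stays_90d,
                 c.companion_delivery_90d, c.no_cni_fourth_month, c.source)
                for pid, c in sorted(self.belatacept_calls.items())]
        return pd.DataFrame(rows, columns=[
            "patient_id", "positive", "index_hospitalization_day", "three_stays_90d",
            "companion_delivery_90d", "no_cni_fourth_month", "source"])

    def regimens_frame(self) -> pd.DataFrame:
        rows = [(pid, p.start, p.end, "|".join(sorted(p.classes)), p.recognized)
                for pid, periods in sorted(self.regimen_periods.items()) for p in periods]
        return pd.DataFrame(rows, columns=["patient_id", "start_day", "end_day", "classes", "recognized"])


def compute_exposure(bundle: ClaimsBundle, cohort: pd.DataFrame) -> ExposureResult:
    """Run every exposure rule for each cohort member."""
    config = bundle.code_config
    deliveries = classify_deliveries(bundle.deliveries, config)
    deliv_by_patient = dict(tuple(deliveries.groupby("patient_id")))
    stays_by_patient = dict(tuple(bundle.stays.groupby("patient_id")))

    timelines: dict[str, ExposureTimeline] = {}
    periods: dict[str, list[RegimenPeriod]] = {}
    switches: dict[str, list[SwitchEvent]] = {}
    calls: dict[str, BelataceptCall] = {}
    initials: dict[str, frozenset[str]] = {}

    for row in cohort.itertuples():
        pid, index_date = row.patient_id, row.index_date
        deliv = deliv_by_patient.get(pid)
        if deliv is not None:
            deliv = deliv.copy()
            deliv["day"] = (deliv["delivery_date"] - index_date).dt.days
            deliv = deliv[deliv["day"] >= 0]
        else:
            deliv = pd.DataFrame(columns=["day", "drug_class"])
        stays = stays_by_patient.get(pid)
        if stays is not None:
            stays = stays.copy()
            stays["day"] = (stays["admission_date"] - index_date).dt.days
            stays = stays[stays["day"] >= 0]
        else:
            stays = pd.DataFrame(columns=[
                "day", "is_chemo_delivery", "principal_diagnosis", "associated_diagnoses"])

        tl = build_timeline(deliv, config, patient_id=pid)
        call = detect_belatacept(stays, deliv, config, patient_id=pid)
        timelines[pid] = tl
        periods[pid] = detect_combinations(tl, config)
        switches[pid] = detect_switches(tl, config, belatacept_call=call)
        calls[pid] = call
        initials[pid] = initial_regimen(tl, call, config)

    logger.info("compute_exposure: %d patients, %d belatacept-positive",
                len(timelines), sum(c.positive for c in calls.values()))
    return ExposureResult(timelines, periods, switches, calls, initials)
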