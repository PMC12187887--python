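"""Paper-shaped reporting: baseline, outcomes, treatment patterns, switches.

Table conventions:

* the treatment table reports, per transplant-era bucket and overall, the
  count and percentage of patients with at least one delivery of each class
  and molecule (or a positive belatacept call) and of each recognized
  combination during follow-up — denominators are all transplanted patients
  of the era;
* yearly prevalence counts a patient as using a class in calendar year Y if
  at least one delivery (or belatacept infusion stay) falls in Y;
* the switch matrix cross-tabulates first relay regimens by origin regimen
  and reports the never-switched fraction.

Every percentage is emitted together with its numerator and denominator so
the tables are recomputable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (BELATACEPT, CNI, ANTIMETABOLITE, MTORI, CORTICOSTEROID,
                     CodeConfig, default_config, group_of)
from .cohort import apply_eligibility, find_index, flag_baseline
from .exposure import ExposureResult, compute_exposure
from .model import ClaimsBundle, classify_deliveries, read_bundle
from .outcomes import compute_outcomes
from .simulate import AGE_CLASSES
from .survival import stratified_outcomes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EraBucket:
    label: str
    start_year: int
    end_year: int

    def contains(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


DEFAULT_ERAS = (
    EraBucket("2009-2011", 2009, 2011),
    EraBucket("2012-2015", 2012, 2015),
    EraBucket("2016-2019", 2016, 2019),
)

_CLASS_ROWS: tuple[tuple[str, str | None], ...] = (
    # (row label, molecule class or None for a group row)
    ("CNI", None),
    ("tacrolimus", "tacrolimus"),
    ("ciclosporin", "ciclosporin"),
    ("corticosteroids", "corticosteroid"),
    ("antimetabolites", None),
    ("mycophenolic_acid", "mycophenolic_acid"),
    ("azathioprine", "azathioprine"),
    ("mTOR_inhibitors", None),
    ("everolimus", "everolimus"),
    ("sirolimus", "sirolimus"),
    ("belatacept", None),
)
_GROUP_FOR_ROW = {"CNI": CNI, "antimetabolites": ANTIMETABOLITE,
                  "mTOR_inhibitors": MTORI, "belatacept": BELATACEPT,
                  "corticosteroids": CORTICOSTEROID}


def _era_of(year: int, eras) -> str | None:
    for era in eras:
        if era.contains(year):
            return era.label
    return None


def _post_index_deliveries(cohort: pd.DataFrame, bundle: ClaimsBundle) -> pd.DataFrame:
    """Classified deliveries of cohort members dated on/after their index."""
    deliveries = classify_deliveries(bundle.deliveries, bundle.code_config)
    index_dates = cohort.set_index("patient_id")["index_date"] if len(cohort) \
        else pd.Series(dtype="datetime64[ns]")
    post = deliveries[deliveries["patient_id"].isin(index_dates.index)].copy()
    if len(post) == 0:
        return post
    return post[post["delivery_date"] >= post["patient_id"].map(index_dates)]


def treatment_table(cohort: pd.DataFrame, bundle: ClaimsBundle,
                    exposure: ExposureResult,
                    eras=DEFAULT_ERAS) -> pd.DataFrame:
    """Treatment-use counts per era of index transplantation and overall.

    Only patients whose index year falls in one of the era buckets enter the
    table (including the overall column denominators).
    """
    config = bundle.code_config
    post = _post_index_deliveries(cohort, bundle)
    classes_by_patient = post.groupby("patient_id")["drug_class"].agg(set).to_dict()

    era_of_patient = {row.patient_id: _era_of(row.index_year, eras)
                      for row in cohort.itertuples()}
    members = {pid for pid, era in era_of_patient.items() if era is not None}

    def patient_has_class(pid: str, row_label: str, molecule: str | None) -> bool:
        classes = classes_by_patient.get(pid, set())
        if molecule is not None:
            return molecule in classes
        group = _GROUP_FOR_ROW[row_label]
        if group == BELATACEPT:
            call = exposure.belatacept_calls.get(pid)
            return bool(call and call.positive) or BELATACEPT in classes
        return any(group_of(c) == group for c in classes)

    combos = sorted(("+".join(sorted(r)) for r in config.recognized_regimens))

    def patient_has_combo(pid: str, combo: str) -> bool:
        want = frozenset(combo.split("+"))
        for p in exposure.regimen_periods.get(pid, []):
            nonsteroid = frozenset(g for g in p.classes if g != CORTICOSTEROID)
            if p.recognized and nonsteroid == want:
                return True
        return False

    rows = []
    buckets = [("overall", members)] + [
        (era.label, {pid for pid in members if era_of_patient[pid] == era.label})
        for era in eras]
    for label, molecule in _CLASS_ROWS:
        for era_label, pids in buckets:
            n = sum(patient_has_class(pid, label, molecule) for pid in pids)
            denom = len(pids)
            rows.append(("class", label, era_label, n, denom,
                         100.0 * n / denom if denom else np.nan))
    any_is = {pid for pid in members
              if classes_by_patient.get(pid) or
              (exposure.belatacept_calls.get(pid) and exposure.belatacept_calls[pid].positive)}
    for era_label, pids in buckets:
        n = len(any_is & pids)
        denom = len(pids)
        rows.append(("class", "at_least_one_IS_drug", era_label, n, denom,
                     100.0 * n / denom if denom else np.nan))
    for combo in combos:
        for era_label, pids in buckets:
            n = sum(patient_has_combo(pid, combo) for pid in pids)
            denom = len(pids)
            rows.append(("combination", combo, era_label, n, denom,
                         100.0 * n / denom if denom else np.nan))
    return pd.DataFrame(rows, columns=["kind", "treatment", "era", "n", "denom", "pct"])


def yearly_prevalence(cohort: pd.DataFrame, bundle: ClaimsBundle,
                      exposure: ExposureResult) -> pd.DataFrame:
    """Distinct patients using each class per calendar year of delivery."""
    post = _post_index_deliveries(cohort, bundle)
    post = post[post["drug_class"] != "other"]
    post["year"] = post["delivery_date"].dt.year
    counts = (post.groupby(["year", "drug_class"])["patient_id"].nunique()
              .rename("n_patients").reset_index())

    # belatacept infusion-stay pattern for algorithm-positive patients
    positive = {pid for pid, c in exposure.belatacept_calls.items() if c.positive}
    stays = bundle.stays
    chemo = stays[(stays["is_chemo_delivery"] == 1) & stays["patient_id"].isin(positive)].copy()
    if len(chemo):
        chemo["year"] = chemo["admission_date"].dt.year
        extra = (chemo.groupby("year")["patient_id"].nunique()
                 .rename("n_patients").reset_index())
        extra["drug_class"] = BELATACEPT
        counts = (pd.concat([counts, extra], ignore_index=True)
                  .groupby(["year", "drug_class"], as_index=False)["n_patients"].max())
    return counts.sort_values(["year", "drug_class"]).reset_index(drop=True)


def switch_matrix(exposure: ExposureResult, cohort: pd.DataFrame) -> dict:
    """First-relay cross-tabulation plus never-switched fraction."""
    first_rows = []
    n_multi = 0
    switched = set()
    for pid, events in exposure.switches.items():
        if not events:
            continue
        switched.add(pid)
        first = events[0]
        first_rows.append((
            "|".join(sorted(first.from_classes)) or "(none)",
            "|".join(sorted(first.to_classes)),
            first.kind))
        if len(events) > 1:
            n_multi += 1
    matrix = (pd.DataFrame(first_rows, columns=["from_regimen", "to_regimen", "kind"])
              .groupby(["from_regimen", "to_regimen", "kind"]).size()
              .rename("n").reset_index()
              if first_rows else
              pd.DataFrame(columns=["from_regimen", "to_regimen", "kind", "n"]))
    n_cohort = len(cohort)
    return {
        "matrix": matrix,
        "n_switched": len(switched),
        "n_multiple_switches": n_multi,
        "never_switched_fraction": 1.0 - len(switched) / n_cohort if n_cohort else np.nan,
    }


def baseline_table(baseline: pd.DataFrame, cohort: pd.DataFrame,
                   eras=DEFAULT_ERAS) -> pd.DataFrame:
    """Baseline flag prevalences over era-bucket members."""
    era_of_patient = {row.patient_id: _era_of(row.index_year, eras)
                      for row in cohort.itertuples()}
    members = baseline[baseline["patient_id"].map(era_of_patient).notna()] \
        if len(baseline) else baseline
    rows = []
    denom = len(members)
    for col in baseline.columns:
        if col == "patient_id":
            continue
        n = int(members[col].sum()) if denom else 0
        rows.append((col, n, denom, 100.0 * n / denom if denom else np.nan))
    return pd.DataFrame(rows, columns=["flag", "n", "denom", "pct"])


@dataclass
class ReportSet:
    baseline_table: pd.DataFrame
    outcome_table: pd.DataFrame
    treatment_table: pd.DataFrame
    yearly_prevalence: pd.DataFrame
    switch_summary: dict
    eligibility: dict
    outcomes: pd.DataFrame
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    run_metadata: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.baseline_table.to_csv(out / "baseline_table.csv", index=False)
        self.outcome_table.to_csv(out / "outcome_table.csv", index=False)
        self.treatment_table.to_csv(out / "treatment_table.csv", index=False)
        self.yearly_prevalence.to_csv(out / "yearly_prevalence.csv", index=False)
        self.switch_summary["matrix"].to_csv(out / "switch_matrix.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        for name, frame in self.curves.items():
            frame.to_csv(out / f"curve_{name}.csv", index=False)
        summary = {
            "eligibility": self.eligibility,
            "switches": {k: v for k, v in self.switch_summary.items() if k != "matrix"},
            "run_metadata": self.run_metadata,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        (out / "summary.txt").write_text(self.text_summary())

    def text_summary(self) -> str:
        lines = ["Pipeline summary", "================", ""]
        lines.append(f"Screened: {self.eligibility['screened']}  "
                     f"eligible: {self.eligibility['eligible']}  "
                     f"excluded: {self.eligibility['excluded']}")
        lines.append("")
        lines.append("Outcome table (5-year probabilities):")
        lines.append(self.outcome_table.to_string(index=False))
        lines.append("")
        sw = self.switch_summary
        lines.append(f"Patients with >=1 relay treatment: {sw['n_switched']} "
                     f"(never switched: {sw['never_switched_fraction']:.3f})")
        return "\n".join(lines) + "\n"


def _config_hash(config: CodeConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def outcome_table(outcomes: pd.DataFrame, cohort: pd.DataFrame,
                  age_class_of: dict[str, str],
                  horizon_years: float = 5.0,
                  index_cutoff: pd.Timestamp | None = None) -> tuple[pd.DataFrame, dict]:
    """Survival summary by age class, restricted to patients with at least
    ``horizon_years`` of potential follow-up (index before ``index_cutoff``)."""
    sub = cohort
    if index_cutoff is not None:
        sub = cohort[cohort["index_date"] < index_cutoff]
    merged = outcomes.merge(sub[["patient_id"]], on="patient_id")
    if len(merged) == 0:
        return pd.DataFrame(columns=["stratum", "n", "event_free_survival",
                                     "event_free_lo", "event_free_hi",
                                     "graft_survival", "graft_lo", "graft_hi"]), {}
    ages = merged["patient_id"].map(age_class_of)
    strata = stratified_outcomes(merged, ages, horizon_years)
    order = ["all"] + [c for c in AGE_CLASSES if c in strata]
    rows = [{"stratum": s, **{k: v for k, v in strata[s].items() if k not in ("km", "aj")}}
            for s in order]
    return pd.DataFrame(rows), strata


def run_pipeline(bundle: ClaimsBundle, eras=DEFAULT_ERAS,
                 horizon_years: float = 5.0,
                 outcome_index_cutoff: str | None = "2015-01-01",
                 seed: int | None = None) -> ReportSet:
    """Execute cohort -> exposure -> outcomes -> survival -> reports."""
    config = bundle.code_config
    index_events, retransplants = find_index(bundle)
    cohort, elig = apply_eligibility(index_events, bundle)
    baseline = flag_baseline(cohort, bundle)
    exposure = compute_exposure(bundle, cohort)
    outcomes = compute_outcomes(bundle, cohort, exposure.timelines, retransplants)

    birth = bundle.patients.set_index("patient_id")["birth_date"]

    def age_class(pid: str, age: int) -> str:
        for label, hi in (("18-29", 29), ("30-39", 39), ("40-49", 49),
                          ("50-59", 59), ("60-69", 69)):
            if age <= hi:
                return label
        return ">=70"

    age_class_of = {row.patient_id: age_class(row.patient_id, row.age_at_index)
                    for row in cohort.itertuples()}
    cutoff = pd.Timestamp(outcome_index_cutoff) if outcome_index_cutoff else None
    out_table, strata = outcome_table(outcomes, cohort, age_class_of,
                                      horizon_years, cutoff)
    curves = {}
    if "all" in strata:
        curves["event_free_all"] = strata["all"]["km"].to_frame()
        curves["competing_all"] = strata["all"]["aj"].to_frame()

    report = ReportSet(
        baseline_table=baseline_table(baseline, cohort, eras),
        outcome_table=out_table,
        treatment_table=treatment_table(cohort, bundle, exposure, eras),
        yearly_prevalence=yearly_prevalence(cohort, bundle, exposure),
        switch_summary=switch_matrix(exposure, cohort),
        eligibility=elig.to_dict(),
        outcomes=outcomes,
        curves=curves,
        run_metadata={
            "config_hash": _config_hash(config),
            "seed": seed,
            "version": __version__,
            "n_patients": int(len(bundle.patients)),
            "n_cohort": int(len(cohort)),
        },
    )
    logger.info("run_pipeline: cohort %d, reports built", len(cohort))
    return report


def run_from_directory(in_dir, out_dir=None, code_config: CodeConfig | None = None,
                       **kwargs) -> ReportSet:
    bundle = read_bundle(in_dir, code_config or default_config())
    report = run_pipeline(bundle, **kwargs)
    if out_dir is not None:
        report.write(out_dir)
    return report
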