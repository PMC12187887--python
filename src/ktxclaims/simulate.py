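"""Synthetic national-claims generator with per-patient ground truth.

Emulates the claim streams a kidney-transplant cohort leaves in an
administrative claims database: an index transplant hospitalization carrying a
procedure code, ICD-10-coded stays, ATC-coded community-pharmacy deliveries at
a roughly monthly cadence, hospital "chemotherapy delivery" stays standing in
for belatacept infusions (invisible by name in community claims), dialysis
sessions, and death dates. Cause-specific hazards for graft loss and death are
constant (exponential), which keeps closed-form oracles available for every
downstream estimator.

The generator emits a :class:`GroundTruth` alongside the claims bundle: the
true regimen timeline, true belatacept status and true event times per
patient. With all noise knobs at zero, every phenotyping rule downstream is
recoverable exactly from the claims, so the ground truth doubles as the
oracle for end-to-end pipeline tests.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfg
from .config import CodeConfig, default_config, group_of
from .model import ClaimsBundle, _coerce_dtypes

DAYS_PER_YEAR = 365.25

AGE_CLASSES = ("18-29", "30-39", "40-49", "50-59", "60-69", ">=70")
_AGE_BOUNDS = {
    "18-29": (18, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-69": (60, 69),
    ">=70": (70, 89),
}

#: Anchor molecules a patient can be relayed to (community-pharmacy visible).
_RELAY_POOL = (cfg.TACROLIMUS, cfg.CICLOSPORIN, cfg.EVEROLIMUS, cfg.SIROLIMUS)
_ANCHOR_GROUPS = {cfg.CNI, cfg.MTORI, cfg.BELATACEPT}

_INELIGIBLE_VARIANTS = ("under_18", "missing_sex", "absent_prior_year", "inconsistent")


@dataclass
class NoiseConfig:
    """Perturbations applied to an ideal claims bundle."""

    missed_delivery_prob: float = 0.0
    extra_chemo_stays_per_patient: float = 0.0
    delivery_delay_max_days: int = 0


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults emulate the cohort the pipeline targets: age distribution and sex
    split of a national kidney-transplant population, per-year cause-specific
    hazards calibrated so the true 5-year survival quantities equal 0.890
    (death-free) and 0.850 (graft-failure-free given the death hazard), a
    ~3.9% belatacept fraction, a ~6.7%/year switching intensity and 30-day
    pharmacy delivery cadence.
    """

    n_patients: int = 1000
    seed: int = 0
    index_period: tuple[int, int] = (2009, 2020)
    age_class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "18-29": 0.068,
            "30-39": 0.124,
            "40-49": 0.191,
            "50-59": 0.249,
            "60-69": 0.247,
            ">=70": 0.121,
        }
    )
    sex_split_male: float = 0.627
    lambda_death: float = 0.023306
    lambda_death_by_age: dict[str, float] | None = None
    lambda_graft: float = 0.034550
    admin_censor_years: float = 12.0
    regimen_mix: dict[str, float] = field(
        default_factory=lambda: {
            "tacrolimus+mycophenolic_acid+corticosteroid": 0.65,
            "ciclosporin+mycophenolic_acid+corticosteroid": 0.13,
            "tacrolimus+everolimus+corticosteroid": 0.07,
            "tacrolimus+mycophenolic_acid": 0.08,
            "everolimus+mycophenolic_acid+corticosteroid": 0.04,
            "tacrolimus+azathioprine+corticosteroid": 0.03,
        }
    )
    switch_rate: float = 0.067
    belatacept_fraction: float = 0.039
    belatacept_regimen: str = "belatacept+mycophenolic_acid+corticosteroid"
    delivery_interval_days: int = 30
    belatacept_stay_spacing_days: int = 30
    dialysis_interval_days: int = 7
    preemptive_fraction: float = 0.132
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.919,
            "dyslipidemia": 0.461,
            "diabetes": 0.196,
            "ischemic_heart_disease": 0.161,
            "obesity_bariatric": 0.115,
            "heart_failure": 0.090,
            "peripheral_artery_disease": 0.071,
            "malnutrition": 0.068,
            "stroke": 0.019,
        }
    )
    ineligible_fraction: float = 0.02
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    min_switch_day: int = 150
    min_observable_days: int = 92

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.lambda_death < 0 or self.lambda_graft < 0:
            raise ValueError("hazards must be >= 0")
        for name, dist in (("age_class_weights", self.age_class_weights),
                           ("regimen_mix", self.regimen_mix)):
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(w < 0 for w in dist.values()):
                raise ValueError(f"{name} has negative weights")
        if not 0 <= self.sex_split_male <= 1:
            raise ValueError("sex_split_male must be in [0, 1]")
        if not 0 <= self.belatacept_fraction <= 1:
            raise ValueError("belatacept_fraction must be in [0, 1]")
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be > 0")


@dataclass
class GroundTruth:
    """True per-patient state emitted by the simulator.

    ``patients`` has one row per simulated patient (index date, age class,
    eligibility, true belatacept status, true event type and times in years
    from index, true switch days). ``timelines`` holds the true regimen
    timeline as half-open ``[start_day, end_day)`` segments of constant
    ``|``-joined class sets.
    """

    patients: pd.DataFrame
    timelines: pd.DataFrame

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(directory / "ground_truth_patients.csv", index=False)
        self.timelines.to_csv(directory / "ground_truth_timelines.csv", index=False)

    @classmethod
    def read(cls, directory) -> "GroundTruth":
        directory = Path(directory)
        patients = pd.read_csv(directory / "ground_truth_patients.csv",
                               parse_dates=["index_date"])
        timelines = pd.read_csv(directory / "ground_truth_timelines.csv")
        return cls(patients, timelines)


# ---------------------------------------------------------------------------
# Competing-risk latent-time sampler
# ---------------------------------------------------------------------------

def event_times(lambda_graft: float, lambda_death: float, horizon: float,
                rng: np.random.Generator) -> tuple[str, float]:
    """Sample time-to-first-event under constant cause-specific hazards.

    The all-cause waiting time is Exponential(lambda_graft + lambda_death);
    the event type is graft vs death with probabilities proportional to the
    cause-specific hazards. Times beyond ``horizon`` are censored there.
    """
    if lambda_graft < 0 or lambda_death < 0:
        raise ValueError("hazards must be >= 0")
    total = lambda_graft + lambda_death
    if total == 0:
        return "censored", float(horizon)
    t = rng.exponential(1.0 / total)
    if t > horizon:
        return "censored", float(horizon)
    if rng.random() < lambda_graft / total:
        return "graft_loss", float(t)
    return "death", float(t)


def sample_competing(n: int, lambda_graft: float, lambda_death: float,
                     horizon: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized version of :func:`event_times`.

    Returns ``(times, codes)`` with codes 0 = censored, 1 = graft loss,
    2 = death.
    """
    total = lambda_graft + lambda_death
    if total == 0:
        return np.full(n, float(horizon)), np.zeros(n, dtype=int)
    t = rng.exponential(1.0 / total, size=n)
    cause = np.where(rng.random(n) < (lambda_graft / total), 1, 2)
    censored = t > horizon
    t = np.where(censored, horizon, t)
    cause = np.where(censored, 0, cause)
    return t, cause


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def _sample_index_date(rng, period: tuple[int, int]) -> datetime.date:
    d0 = datetime.date(period[0], 1, 1).toordinal()
    d1 = datetime.date(period[1], 12, 31).toordinal()
    return datetime.date.fromordinal(int(rng.integers(d0, d1 + 1)))


def _choice(rng, dist: dict[str, float]) -> str:
    keys = sorted(dist)
    weights = np.array([dist[k] for k in keys], dtype=float)
    weights = weights / weights.sum()
    return keys[int(rng.choice(len(keys), p=weights))]


def _regimen_classes(name: str) -> frozenset[str]:
    return frozenset(name.split("+"))


def _relay(current: frozenset[str], used: set[str], rng) -> frozenset[str] | None:
    pool = sorted(set(_RELAY_POOL) - used)
    if not pool:
        return None
    new_anchor = pool[int(rng.integers(len(pool)))]
    companions = {c for c in current if group_of(c) not in _ANCHOR_GROUPS}
    return frozenset(companions | {new_anchor})


def generate(sim_config: SimConfig, code_config: CodeConfig | None = None
             ) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a claims bundle and its ground truth.

    Determinism: one RNG substream per patient, keyed by ``(seed, i)``, so a
    given patient's stream is invariant to ``n_patients``.
    """
    sim_config.validate()
    code_config = code_config or default_config()
    w = code_config.windows
    noise = sim_config.noise

    pat_rows: list[tuple] = []
    stay_rows: list[tuple] = []
    deliv_rows: list[tuple] = []
    dial_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    tl_rows: list[tuple] = []

    study_end = code_config.study_end
    dpy = DAYS_PER_YEAR

    for i in range(sim_config.n_patients):
        rng = np.random.default_rng([sim_config.seed, i])
        pid = f"P{i:06d}"

        index_date = _sample_index_date(rng, sim_config.index_period)
        age_class = _choice(rng, sim_config.age_class_weights)
        lo, hi = _AGE_BOUNDS[age_class]
        age = int(rng.integers(lo, hi + 1))
        birth_date = index_date - datetime.timedelta(
            days=int(round(age * dpy)) + int(rng.integers(0, 365)))
        sex = "male" if rng.random() < sim_config.sex_split_male else "female"

        ineligible_reason = ""
        if rng.random() < sim_config.ineligible_fraction:
            ineligible_reason = _INELIGIBLE_VARIANTS[int(rng.integers(len(_INELIGIBLE_VARIANTS)))]
        if ineligible_reason == "under_18":
            age = 17
            age_class = "18-29"
            birth_date = index_date - datetime.timedelta(
                days=int(round(17 * dpy)) + int(rng.integers(0, 300)))
        if ineligible_reason == "missing_sex":
            sex = "missing"

        horizon_days = min(int(round(sim_config.admin_censor_years * dpy)),
                           (study_end - index_date).days)
        horizon_days = max(horizon_days, 1)

        lam_d = sim_config.lambda_death
        if sim_config.lambda_death_by_age:
            lam_d = sim_config.lambda_death_by_age.get(age_class, lam_d)
        event, t_years = event_times(sim_config.lambda_graft, lam_d,
                                     horizon_days / dpy, rng)
        e_day = horizon_days if event == "censored" else max(1, int(round(t_years * dpy)))
        # A graft loss too close to the censoring horizon leaves no observable
        # treatment gap or qualifying dialysis run; treat it as censored.
        if event == "graft_loss" and horizon_days - e_day < sim_config.min_observable_days:
            event, e_day = "censored", horizon_days

        # --- true regimen timeline -------------------------------------
        # A belatacept maintenance needs at least three infusion stays on the
        # books to be claims-visible; patients whose follow-up ends before the
        # third infusion draw a pharmacy-visible regimen instead.
        bela_floor = 2 * sim_config.belatacept_stay_spacing_days + 1
        if rng.random() < sim_config.belatacept_fraction and e_day >= bela_floor:
            initial = _regimen_classes(sim_config.belatacept_regimen)
        else:
            initial = _regimen_classes(_choice(rng, sim_config.regimen_mix))

        switch_days: list[int] = []
        segments: list[tuple[frozenset[str], int, int]] = []
        used = {c for c in initial if c in _RELAY_POOL}
        current = initial
        t_switch = 0.0
        prev_day = 0
        if sim_config.switch_rate > 0:
            while True:
                t_switch += rng.exponential(1.0 / sim_config.switch_rate)
                day = int(round(t_switch * dpy))
                if day > e_day - 31:
                    break
                if day < sim_config.min_switch_day or day <= prev_day:
                    continue
                relay = _relay(current, used, rng)
                if relay is None:
                    break
                segments.append((current, prev_day, day))
                switch_days.append(day)
                used |= {c for c in relay if c in _RELAY_POOL}
                current = relay
                prev_day = day
        segments.append((current, prev_day, e_day))

        is_belatacept = any(cfg.BELATACEPT in seg[0] for seg in segments)

        # --- pre-index claims -------------------------------------------
        emit_preindex = ineligible_reason != "absent_prior_year"
        preemptive = rng.random() < sim_config.preemptive_fraction
        if emit_preindex:
            day = -int(rng.integers(30, 331))
            deliv_rows.append((pid, index_date + datetime.timedelta(days=day),
                               "C09AA05", ""))
            for cond in sorted(sim_config.comorbidity_prevalence):
                if rng.random() < sim_config.comorbidity_prevalence[cond]:
                    prefixes = code_config.comorbidity_codelists.get(cond)
                    if not prefixes:
                        continue
                    d = index_date - datetime.timedelta(days=int(rng.integers(30, 360)))
                    stay_rows.append((pid, d, d, "", prefixes[0] + "0", "", 0))
            if not preemptive:
                for day in range(-200, -19, 14):
                    dial_rows.append((pid, index_date + datetime.timedelta(days=day)))

        # --- death / index stay -----------------------------------------
        death_date = pd.NaT
        if event == "death":
            death_date = index_date + datetime.timedelta(days=e_day)
        if ineligible_reason == "inconsistent":
            death_date = index_date - datetime.timedelta(days=30)

        procedure = sorted(code_config.transplant_procedure_codes)[
            int(rng.integers(len(code_config.transplant_procedure_codes)))]
        discharge = index_date + datetime.timedelta(days=10)
        if event == "death":
            discharge = min(discharge, index_date + datetime.timedelta(days=e_day))
        stay_rows.append((pid, index_date, discharge, procedure, "N185", "", 0))

        # --- deliveries / infusion stays --------------------------------
        class_intervals: dict[str, list[tuple[int, int]]] = {}
        for classes, a, b in segments:
            for c in classes:
                ivs = class_intervals.setdefault(c, [])
                if ivs and ivs[-1][1] == a:
                    ivs[-1] = (ivs[-1][0], b)
                else:
                    ivs.append((a, b))

        step = sim_config.delivery_interval_days
        for c in sorted(class_intervals):
            if c == cfg.BELATACEPT:
                continue
            atc = code_config.atc_for_class(c)
            for a, b in class_intervals[c]:
                for day in range(a, b, step):
                    if noise.missed_delivery_prob > 0 and rng.random() < noise.missed_delivery_prob:
                        continue
                    if noise.delivery_delay_max_days > 0:
                        day = day + int(rng.integers(0, noise.delivery_delay_max_days + 1))
                    deliv_rows.append((pid, index_date + datetime.timedelta(days=day), atc, ""))

        if cfg.BELATACEPT in class_intervals:
            dx = code_config.transplant_diagnosis_codes[0]
            bela_atc = code_config.atc_for_class(cfg.BELATACEPT)
            for a, b in class_intervals[cfg.BELATACEPT]:
                for day in range(a, b, sim_config.belatacept_stay_spacing_days):
                    d = index_date + datetime.timedelta(days=day)
                    stay_rows.append((pid, d, d, "", "Z511", dx, 1))
                    if d >= code_config.retrocession_start:
                        deliv_rows.append((pid, d, bela_atc, ""))

        # --- noise: non-qualifying chemo-delivery stays ------------------
        if noise.extra_chemo_stays_per_patient > 0:
            for _ in range(rng.poisson(noise.extra_chemo_stays_per_patient)):
                d = index_date + datetime.timedelta(days=int(rng.integers(0, max(e_day, 1))))
                stay_rows.append((pid, d, d, "", "C64", "", 1))

        # --- post-graft-loss dialysis -----------------------------------
        if event == "graft_loss":
            for day in range(e_day, horizon_days + 1, sim_config.dialysis_interval_days):
                dial_rows.append((pid, index_date + datetime.timedelta(days=day)))

        pat_rows.append((pid, birth_date, sex, death_date))
        truth_rows.append((
            pid, pd.Timestamp(index_date), age_class, age, sex,
            ineligible_reason == "", ineligible_reason, is_belatacept,
            "|".join(sorted(segments[0][0])), event,
            round(e_day / dpy, 6),
            round(e_day / dpy, 6) if event == "graft_loss" else np.nan,
            round(e_day / dpy, 6) if event == "death" else np.nan,
            round(horizon_days / dpy, 6),
            "|".join(str(d) for d in switch_days),
        ))
        for classes, a, b in segments:
            tl_rows.append((pid, "|".join(sorted(classes)), a, b))

    patients = pd.DataFrame(pat_rows, columns=["patient_id", "birth_date", "sex", "death_date"])
    stays = pd.DataFrame(stay_rows, columns=[
        "patient_id", "admission_date", "discharge_date", "procedure_codes",
        "principal_diagnosis", "associated_diagnoses", "is_chemo_delivery"])
    deliveries = pd.DataFrame(deliv_rows, columns=[
        "patient_id", "delivery_date", "atc_code", "presentation_id"])
    dialysis = pd.DataFrame(dial_rows, columns=["patient_id", "session_date"])

    bundle = ClaimsBundle(
        patients=_coerce_dtypes("patients", patients),
        stays=_coerce_dtypes("stays", stays),
        deliveries=_coerce_dtypes("deliveries", deliveries),
        dialysis=_coerce_dtypes("dialysis", dialysis),
        code_config=code_config,
    )
    truth_patients = pd.DataFrame(truth_rows, columns=[
        "patient_id", "index_date", "age_class", "age_at_index", "sex",
        "eligible", "ineligible_reason", "belatacept", "initial_regimen",
        "event", "event_time_years", "graft_loss_time_years",
        "death_time_years", "censor_time_years", "switch_days"])
    truth_timelines = pd.DataFrame(tl_rows, columns=["patient_id", "classes", "start_day", "end_day"])
    return bundle, GroundTruth(truth_patients, truth_timelines)


def corrupt(bundle: ClaimsBundle, truth: GroundTruth, noise_config: NoiseConfig,
            rng: np.random.Generator) -> ClaimsBundle:
    """Apply noise to a generated bundle without touching the ground truth."""
    deliveries = bundle.deliveries.copy()
    if noise_config.missed_delivery_prob > 0:
        keep = rng.random(len(deliveries)) >= noise_config.missed_delivery_prob
        deliveries = deliveries[keep].reset_index(drop=True)
    if noise_config.delivery_delay_max_days > 0 and len(deliveries):
        delays = rng.integers(0, noise_config.delivery_delay_max_days + 1, size=len(deliveries))
        deliveries["delivery_date"] = deliveries["delivery_date"] + pd.to_timedelta(delays, unit="D")
    stays = bundle.stays
    if noise_config.extra_chemo_stays_per_patient > 0 and len(truth.patients):
        extra = []
        for _, row in truth.patients.iterrows():
            for _ in range(rng.poisson(noise_config.extra_chemo_stays_per_patient)):
                day = int(rng.integers(0, max(int(row["event_time_years"] * DAYS_PER_YEAR), 1)))
                d = pd.Timestamp(row["index_date"]) + pd.Timedelta(days=day)
                extra.append((row["patient_id"], d, d, "", "C64", "", 1))
        if extra:
            stays = pd.concat([stays, pd.DataFrame(extra, columns=stays.columns)],
                              ignore_index=True)
    return dataclasses.replace(bundle, deliveries=deliveries, stays=stays)
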