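"""Product-limit and Aalen-Johansen estimators with 95% confidence bands.

Both estimators are written as small fit-style classes: construct with
options, call ``fit(durations, events)``, read trailing-underscore attributes.

* :class:`KaplanMeierEstimator` — S(t) = prod_{t_i <= t} (1 - d_i / n_i) with
  Greenwood variance; the default band applies the log(-log) transform so the
  interval respects [0, 1].
* :class:`AalenJohansenEstimator` — cause-specific cumulative incidence
  F_k(t) = sum_{t_i <= t} S(t_i-) d_ki / n_i in the presence of competing
  risks, with the standard counting-process (Marubini-Valsecchi) variance.
  Ties across causes at the same time are processed against the same
  pre-time risk set. The estimator satisfies the identity
  sum_k F_k(t) + S(t) = 1 at every event time, with S the all-cause
  product-limit survival.

Durations are in years throughout the pipeline (days / 365.25).
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm


def _validate(durations, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("durations must be a non-empty 1-d array")
    if len(t) != len(e):
        raise ValueError("durations and events must have equal length")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("durations must be finite and >= 0")
    return t, e


def _counts(durations: np.ndarray, flags: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique event times, at-risk counts and event counts (ties pooled)."""
    order = np.argsort(durations, kind="mergesort")
    t, e = durations[order], flags[order]
    te = np.sort(t[e])
    times = np.unique(te)
    n = len(t)
    # number still at risk just before each event time
    at_risk = n - np.searchsorted(t, times, side="left")
    d = (np.searchsorted(te, times, side="right")
         - np.searchsorted(te, times, side="left"))
    return times, at_risk, d


def _step_eval(grid: np.ndarray, values: np.ndarray, t, fill: float):
    """Right-continuous step evaluation with value `fill` before grid[0]."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("evaluation times must be >= 0")
    if len(values) == 0:
        out = np.full(t_arr.shape, fill)
    else:
        idx = np.searchsorted(grid, t_arr, side="right") - 1
        out = np.where(idx < 0, fill, values[np.clip(idx, 0, len(values) - 1)])
    return out if out.ndim else float(out)


class KaplanMeierEstimator:
    """Product-limit estimator of the survival function.

    Parameters
    ----------
    alpha : float
        Two-sided confidence level is ``1 - alpha`` (default 95%).
    ci_method : str
        ``"log-log"`` (default; interval on the log(-log S) scale) or
        ``"greenwood"`` (plain Wald interval, clipped to [0, 1]).
    """

    def __init__(self, alpha: float = 0.05, ci_method: str = "log-log"):
        if ci_method not in ("log-log", "greenwood"):
            raise ValueError("ci_method must be 'log-log' or 'greenwood'")
        self.alpha = alpha
        self.ci_method = ci_method

    def get_params(self) -> dict:
        return {"alpha": self.alpha, "ci_method": self.ci_method}

    def fit(self, durations, event_observed) -> "KaplanMeierEstimator":
        durations, events = _validate(durations, event_observed)
        events = np.asarray(events).astype(bool)
        times, n, d = _counts(durations, events)

        with np.errstate(divide="ignore", invalid="ignore"):
            frac = 1.0 - d / n
            survival = np.cumprod(frac)
            # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
            gw_terms = np.where(n > d, d / (n * (n - d)), np.nan)
            cum_gw = np.cumsum(gw_terms)
            variance = survival**2 * cum_gw

            z = norm.ppf(1 - self.alpha / 2)
            if self.ci_method == "log-log":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    theta = z * np.sqrt(cum_gw) / np.log(survival)
                    lo = survival ** np.exp(-theta)
                    hi = survival ** np.exp(theta)
            else:
                half = z * np.sqrt(variance)
                lo = np.clip(survival - half, 0.0, 1.0)
                hi = np.clip(survival + half, 0.0, 1.0)
            lo = np.where(survival == 0.0, 0.0, lo)
            hi = np.where(survival == 0.0, 0.0, hi)

        self.n_subjects_ = len(durations)
        self.event_times_ = times
        self.n_at_risk_ = n
        self.n_events_ = d
        self.survival_ = survival
        self.variance_ = variance
        self.ci_lower_ = lo
        self.ci_upper_ = hi
        return self

    def survival_at(self, t) -> tuple:
        """(estimate, lower, upper) of S at time(s) t (right-continuous)."""
        return (
            _step_eval(self.event_times_, self.survival_, t, 1.0),
            _step_eval(self.event_times_, self.ci_lower_, t, 1.0),
            _step_eval(self.event_times_, self.ci_upper_, t, 1.0),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times_,
            "estimate": self.survival_,
            "lo": self.ci_lower_,
            "hi": self.ci_upper_,
            "at_risk": self.n_at_risk_,
            "events": self.n_events_,
        })


class AalenJohansenEstimator:
    """Aalen-Johansen cumulative incidence with competing risks.

    Event codes: 0 censored, positive integers for causes (1 = event of
    interest, 2 = competing death, by the pipeline convention, but any set of
    positive codes works).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def get_params(self) -> dict:
        return {"alpha": self.alpha}

    def fit(self, durations, event_codes) -> "AalenJohansenEstimator":
        durations, codes = _validate(durations, event_codes)
        codes = np.asarray(codes, dtype=int)
        if np.any(codes < 0):
            raise ValueError("event codes must be >= 0 (0 = censored)")
        causes = sorted(int(c) for c in np.unique(codes) if c != 0)

        any_event = codes > 0
        times, n, d_all = _counts(durations, any_event)
        order = np.argsort(durations, kind="mergesort")
        t_sorted, c_sorted = durations[order], codes[order]

        surv = np.cumprod(1.0 - d_all / n)
        surv_prev = np.concatenate([[1.0], surv[:-1]])  # S(t-)

        z = norm.ppf(1 - self.alpha / 2)
        cif: dict[int, np.ndarray] = {}
        var: dict[int, np.ndarray] = {}
        lo: dict[int, np.ndarray] = {}
        hi: dict[int, np.ndarray] = {}
        with np.errstate(divide="ignore", invalid="ignore"):
            safe_nd = np.where(n > d_all, n * (n - d_all), np.inf)
            for k in causes:
                tk = np.sort(t_sorted[c_sorted == k])
                d_k = (np.searchsorted(tk, times, side="right")
                       - np.searchsorted(tk, times, side="left"))
                jumps = surv_prev * d_k / n
                F = np.cumsum(jumps)
                # counting-process variance (Marubini & Valsecchi form),
                # expanded into cumulative sums for O(m) evaluation
                a = d_all / safe_nd
                A = np.cumsum(a)
                B = np.cumsum(F * a)
                C = np.cumsum(F**2 * a)
                D = np.cumsum(surv_prev**2 * (n - d_k) / n * d_k / n**2)
                E = np.cumsum(surv_prev * d_k / n**2)
                G = np.cumsum(F * surv_prev * d_k / n**2)
                v = (F**2 * A - 2 * F * B + C) + D - 2 * (F * E - G)
                v = np.maximum(v, 0.0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    # log(-log) style interval on the CIF scale
                    theta = z * np.sqrt(v) / (F * np.log(F))
                    lo_k = F ** np.exp(-theta)
                    hi_k = F ** np.exp(theta)
                lo_k = np.where(F == 0.0, 0.0, lo_k)
                hi_k = np.where(F == 0.0, 0.0, hi_k)
                cif[k], var[k] = F, v
                lo[k], hi[k] = np.minimum(lo_k, hi_k), np.maximum(lo_k, hi_k)

        self.n_subjects_ = len(durations)
        self.causes_ = causes
        self.event_times_ = times
        self.n_at_risk_ = n
        self.n_events_all_ = d_all
        self.overall_survival_ = surv
        self.cif_ = cif
        self.variance_ = var
        self.ci_lower_ = lo
        self.ci_upper_ = hi
        return self

    def cif_at(self, cause: int, t) -> tuple:
        """(estimate, lower, upper) of F_cause at time(s) t."""
        if cause not in self.cif_:
            zero = np.zeros_like(np.asarray(t, dtype=float))
            return zero, zero, zero
        return (
            _step_eval(self.event_times_, self.cif_[cause], t, 0.0),
            _step_eval(self.event_times_, self.ci_lower_[cause], t, 0.0),
            _step_eval(self.event_times_, self.ci_upper_[cause], t, 0.0),
        )

    def survival_from_cause_at(self, cause: int, t) -> tuple:
        """1 - F_cause at t: event-specific 'survival' (e.g. graft survival).

        The band is the complement of the CIF band, so lower <= estimate <=
        upper.
        """
        est, lo, hi = self.cif_at(cause, t)
        return 1.0 - est, 1.0 - hi, 1.0 - lo

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.event_times_, "overall_survival": self.overall_survival_,
                "at_risk": self.n_at_risk_, "events": self.n_events_all_}
        for k in self.causes_:
            data[f"cif_{k}"] = self.cif_[k]
            data[f"cif_{k}_lo"] = self.ci_lower_[k]
            data[f"cif_{k}_hi"] = self.ci_upper_[k]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Functional wrappers and stratified summaries
# ---------------------------------------------------------------------------

def km_fit(durations, event_observed, alpha: float = 0.05,
           ci_method: str = "log-log") -> KaplanMeierEstimator:
    return KaplanMeierEstimator(alpha=alpha, ci_method=ci_method).fit(durations, event_observed)


def aj_fit(durations, event_codes, alpha: float = 0.05) -> AalenJohansenEstimator:
    return AalenJohansenEstimator(alpha=alpha).fit(durations, event_codes)


def survival_at(curve, t) -> tuple:
    """Evaluate a fitted KM curve at t (right-continuous step function)."""
    return curve.survival_at(t)


def outcome_summary(outcomes: pd.DataFrame, horizon_years: float = 5.0) -> dict:
    """Event-free and graft-survival summary of an outcome table.

    Event-free survival treats any event (graft loss or death) as the
    endpoint of a product-limit fit; graft survival is one minus the
    Aalen-Johansen cumulative incidence of graft loss with death competing.
    """
    times = outcomes["time_years"].to_numpy()
    codes = outcomes["event_code"].to_numpy()
    km = km_fit(times, codes > 0)
    aj = aj_fit(times, codes)
    s, s_lo, s_hi = km.survival_at(horizon_years)
    g, g_lo, g_hi = aj.survival_from_cause_at(1, horizon_years)
    return {
        "n": int(len(outcomes)),
        "event_free_survival": float(s), "event_free_lo": float(s_lo), "event_free_hi": float(s_hi),
        "graft_survival": float(g), "graft_lo": float(g_lo), "graft_hi": float(g_hi),
        "km": km, "aj": aj,
    }


def stratified_outcomes(outcomes: pd.DataFrame, age_classes: pd.Series | Iterable,
                        horizon_years: float = 5.0) -> dict[str, dict]:
    """Per-age-class (plus pooled "all") survival summaries.

    Empty strata are skipped with a warning.
    """
    age = pd.Series(list(age_classes), index=outcomes.index)
    results: dict[str, dict] = {"all": outcome_summary(outcomes, horizon_years)}
    for stratum in sorted(age.dropna().unique()):
        sub = outcomes[age == stratum]
        if len(sub) == 0:
            warnings.warn(f"empty stratum {stratum!r} skipped")
            continue
        results[str(stratum)] = outcome_summary(sub, horizon_years)
    return results
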