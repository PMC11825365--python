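"""Signal-detection and engagement metrics for rCPT sessions.

Per time bin and per session the module computes the standard measures:

    hit rate            HR  = hits / (hits + misses)
    false alarm rate    FAR = false alarms / (false alarms + correct rejections)
    sensitivity         d'  = z(HR) - z(FAR)
    response criterion  c   = -(z(HR) + z(FAR)) / 2
    impulsivity %           = 100 * centre ITI touches / total ITIs initiated
    response rate           = (hits + FA) / (hits + FA + misses + CR)

where z is the standard normal quantile.  Extreme rates (exactly 0 or 1)
make z infinite; the default correction maps 0 to 1/(2N) and 1 to
1 - 1/(2N) with N the number of trials of that stimulus class (method
``half_count``); method ``none`` propagates them as missing with a warning.
Latency summaries use the sample SD (N-1).  Correction trials are excluded
from all of the above and tallied separately.

Stage-advancement criteria are pure functions over session summaries:
Stage 1/2 advance on >= 60 rewards in a 45-min session; Stage 3 promotes
after d' > 0.6 on two consecutive sessions with at least seven sessions
completed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trials import BinSpec

log = logging.getLogger(__name__)

COUNT_COLUMNS = ("hits", "misses", "false_alarms", "correct_rejections",
                 "correction_trials", "correction_responses",
                 "iti_touches", "itis_initiated", "rewards")


@dataclass(frozen=True)
class RateCorrection:
    """How to handle hit/false-alarm rates of exactly 0 or 1."""

    method: str = "half_count"

    def __post_init__(self) -> None:
        if self.method not in ("none", "half_count"):
            raise ValueError(f"unknown rate correction {self.method!r}")

    def apply(self, rate: float, n: int) -> float:
        if self.method == "none" or not np.isfinite(rate) or n <= 0:
            return rate
        if rate == 0.0:
            return 1.0 / (2 * n)
        if rate == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate


def tally(trials: pd.DataFrame, events: pd.DataFrame, bins: BinSpec,
          count_iti_restarts: bool = True) -> pd.DataFrame:
    """Outcome and engagement counts per time bin.

    Correction-trial outcomes are tallied in their own columns and never
    enter the hit/miss/FA/CR counts.  An ITI follows every trial outcome;
    with ``count_iti_restarts`` each ITI touch restarts the interval and
    counts as a further initiation (the default denominator for
    impulsivity %), otherwise only the initial ITIs count.
    """
    main = trials[~trials["is_correction"]]
    corr = trials[trials["is_correction"]]
    out = pd.DataFrame({"bin_index": np.arange(bins.n_bins)})
    mb = bins.assign(main["onset"]) if len(main) else np.array([], int)
    cb = bins.assign(corr["onset"]) if len(corr) else np.array([], int)
    for name, oc in (("hits", "hit"), ("misses", "miss"),
                     ("false_alarms", "false_alarm"),
                     ("correct_rejections", "correct_rejection")):
        sel = (main["outcome"] == oc).to_numpy()
        out[name] = np.bincount(mb[sel], minlength=bins.n_bins) if sel.any() \
            else np.zeros(bins.n_bins, int)
    out["correction_trials"] = (np.bincount(cb, minlength=bins.n_bins)
                                if len(corr) else np.zeros(bins.n_bins, int))
    sel = (corr["outcome"] == "false_alarm").to_numpy() if len(corr) else None
    out["correction_responses"] = (
        np.bincount(cb[sel], minlength=bins.n_bins)
        if sel is not None and sel.any() else np.zeros(bins.n_bins, int))

    touches = events[events["event"] == "iti_touch"]
    tb = bins.assign(touches["timestamp_s"]) if len(touches) else np.array([], int)
    out["iti_touches"] = (np.bincount(tb, minlength=bins.n_bins)
                          if len(touches) else np.zeros(bins.n_bins, int))
    # every trial outcome (corrections included) initiates an ITI
    ob = bins.assign(trials["outcome_time"]) if len(trials) else np.array([], int)
    initiated = (np.bincount(ob, minlength=bins.n_bins)
                 if len(trials) else np.zeros(bins.n_bins, int))
    if count_iti_restarts:
        initiated = initiated + out["iti_touches"].to_numpy()
    out["itis_initiated"] = initiated

    rewards = events[events["event"] == "reward_delivered"]
    rb = bins.assign(rewards["timestamp_s"]) if len(rewards) else np.array([], int)
    out["rewards"] = (np.bincount(rb, minlength=bins.n_bins)
                      if len(rewards) else np.zeros(bins.n_bins, int))
    return out


def hit_rate(counts) -> float:
    n = counts["hits"] + counts["misses"]
    return counts["hits"] / n if n > 0 else np.nan


def false_alarm_rate(counts) -> float:
    n = counts["false_alarms"] + counts["correct_rejections"]
    return counts["false_alarms"] / n if n > 0 else np.nan


def d_prime(hr: float, far: float,
            correction: RateCorrection = RateCorrection(),
            n_signal: int = 0, n_noise: int = 0) -> float:
    """Sensitivity z(HR) - z(FAR) on the (possibly corrected) rates."""
    hr = correction.apply(hr, n_signal)
    far = correction.apply(far, n_noise)
    if not (np.isfinite(hr) and np.isfinite(far)):
        return np.nan
    v = float(norm.ppf(hr) - norm.ppf(far))
    if not np.isfinite(v):
        log.warning("d' infinite for HR=%s FAR=%s with no rate correction", hr, far)
        return np.nan
    return v


def criterion(hr: float, far: float,
              correction: RateCorrection = RateCorrection(),
              n_signal: int = 0, n_noise: int = 0) -> float:
    """Response criterion -(z(HR) + z(FAR))/2; positive = conservative."""
    hr = correction.apply(hr, n_signal)
    far = correction.apply(far, n_noise)
    if not (np.isfinite(hr) and np.isfinite(far)):
        return np.nan
    v = float(-(norm.ppf(hr) + norm.ppf(far)) / 2.0)
    if not np.isfinite(v):
        log.warning("criterion infinite for HR=%s FAR=%s", hr, far)
        return np.nan
    return v


def impulsivity_pct(counts) -> float:
    if counts["itis_initiated"] <= 0:
        return np.nan
    return 100.0 * counts["iti_touches"] / counts["itis_initiated"]


def response_rate(counts) -> float:
    total = (counts["hits"] + counts["false_alarms"]
             + counts["misses"] + counts["correct_rejections"])
    if total <= 0:
        return np.nan
    return (counts["hits"] + counts["false_alarms"]) / total


def latency_stats(trials: pd.DataFrame, bins: BinSpec) -> pd.DataFrame:
    """Mean and sample SD of correct, incorrect and reward latencies per bin.

    "Correct" latencies are hit response latencies, "incorrect" are
    false-alarm response latencies (non-correction trials only); a
    single-latency bin reports its mean with a missing SD.
    """
    main = trials[~trials["is_correction"]].assign(
        bin_index=lambda d: bins.assign(d["onset"]))
    rows = []
    for b in range(bins.n_bins):
        sub = main[main["bin_index"] == b]
        row = {"bin_index": b}
        for label, series in (
                ("correct_latency",
                 sub.loc[sub["outcome"] == "hit", "response_latency"]),
                ("incorrect_latency",
                 sub.loc[sub["outcome"] == "false_alarm", "response_latency"]),
                ("reward_latency", sub["reward_latency"])):
            vals = series.dropna().to_numpy(float)
            row[f"{label}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{label}_sd"] = (float(vals.std(ddof=1))
                                  if vals.size > 1 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def bin_summaries(trials: pd.DataFrame, events: pd.DataFrame, bins: BinSpec,
                  trial_orient: pd.DataFrame | None = None,
                  correction: RateCorrection = RateCorrection(),
                  count_iti_restarts: bool = True) -> pd.DataFrame:
    """One row per time bin with counts, SDT metrics, latencies, orientation."""
    counts = tally(trials, events, bins, count_iti_restarts=count_iti_restarts)
    lat = latency_stats(trials, bins)
    rows = []
    for _, c in counts.iterrows():
        hr, far = hit_rate(c), false_alarm_rate(c)
        n_sig = int(c["hits"] + c["misses"])
        n_noise = int(c["false_alarms"] + c["correct_rejections"])
        rows.append({
            "bin_index": int(c["bin_index"]),
            "hit_rate": hr, "false_alarm_rate": far,
            "d_prime": d_prime(hr, far, correction, n_sig, n_noise),
            "criterion": criterion(hr, far, correction, n_sig, n_noise),
            "impulsivity_pct": impulsivity_pct(c),
            "response_rate": response_rate(c),
        })
    out = counts.merge(pd.DataFrame(rows), on="bin_index")
    out = out.merge(lat, on="bin_index")
    if trial_orient is not None:
        from .trials import orientation_index
        oi = orientation_index(trial_orient, trials, bins)
        out = out.merge(
            oi[["bin_index", "n_indeterminate", "orientation_index"]],
            on="bin_index")
    return out


def session_report(summary: pd.DataFrame, subject: str = "sim",
                   session: str = "s1") -> pd.DataFrame:
    """Tidy long-format table: one row per subject-session-bin-metric."""
    metrics = [c for c in summary.columns if c != "bin_index"]
    long = summary.melt(id_vars="bin_index", value_vars=metrics,
                        var_name="metric", value_name="value")
    long.insert(0, "subject", subject)
    long.insert(1, "session", session)
    return long.sort_values(["metric", "bin_index"]).reset_index(drop=True)


def stage12_advances(rewards: int, session_duration: float = 45 * 60.0,
                     required_rewards: int = 60) -> bool:
    """Stage 1/2 criterion: >= 60 rewards within a 45-min session."""
    return session_duration <= 45 * 60.0 + 1e-9 and rewards >= required_rewards


def stage3_promotion_session(d_primes, threshold: float = 0.6,
                             min_sessions: int = 7) -> int | None:
    """First (1-based) session at which the Stage-3 criterion fires.

    Requires d' > threshold on that session and the one before, and at
    least ``min_sessions`` sessions completed; None when never met.
    """
    d = list(d_primes)
    for k in range(1, len(d)):
        if d[k] > threshold and d[k - 1] > threshold and (k + 1) >= min_sessions:
            return k + 1
    return None
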