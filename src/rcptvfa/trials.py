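"""Trial construction from event logs and trial-level orientation.

A trial is one stimulus presentation paired with the next of the four
outcome events (hit, miss, false alarm, correct rejection) before the next
stimulus onset; its limited-hold window runs from stimulus onset to the
outcome timestamp.  Response latency is outcome minus onset for touches;
reward latency is the tray entry minus the hit.  A trial is "oriented" when
at least one QC-valid video frame inside its window (half-open
[onset, outcome)) is classified oriented; a trial with zero valid frames is
indeterminate and excluded from both numerator and denominator of the
orientation index, with its count reported.

The orientation index of a time bin is the number of oriented trials
divided by the number of trials whose onset falls in that bin (bins are
half-open [k*w, (k+1)*w), default width 900 s, i.e. 15 min).  Correction
trials are excluded from the denominators by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import OUTCOME_EVENTS, SessionSchedule

log = logging.getLogger(__name__)

_STIM_EVENTS = {"stim_on_splus": ("S+", False), "stim_on_sminus": ("S-", False),
                "correction_stim_on": ("S-", True)}


class TrialStructureError(ValueError):
    """The event log cannot be parsed into well-formed trials."""


@dataclass(frozen=True)
class BinSpec:
    """Half-open analysis bins over session time."""

    bin_width: float = 900.0
    session_duration: float = 90 * 60.0

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")
        if not self.session_duration > 0:
            raise ValueError("session_duration must be > 0")

    @property
    def n_bins(self) -> int:
        return int(math.ceil(self.session_duration / self.bin_width))

    def assign(self, t) -> np.ndarray:
        """Bin index for onset time(s); the final bin absorbs t == duration."""
        idx = np.floor(np.asarray(t, float) / self.bin_width).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)


def build_trials(events: pd.DataFrame, schedule: SessionSchedule) -> pd.DataFrame:
    """Pair each stimulus onset with its outcome; compute latencies.

    Raises :class:`TrialStructureError` (naming the timestamp) for a
    stimulus with no outcome before the next stimulus, or an outcome with
    no preceding stimulus.
    """
    rows = []
    open_trial: dict | None = None
    pending_hit: dict | None = None
    for row in events.itertuples(index=False):
        ev = row.event
        if ev in _STIM_EVENTS:
            if open_trial is not None:
                raise TrialStructureError(
                    f"stimulus at t={open_trial['onset']:.3f} s has no outcome "
                    f"before the next stimulus at t={row.timestamp_s:.3f} s")
            stimulus, is_corr = _STIM_EVENTS[ev]
            open_trial = dict(trial_id=row.trial_id, stimulus=stimulus,
                              onset=float(row.timestamp_s), is_correction=is_corr)
            pending_hit = None
        elif ev in OUTCOME_EVENTS:
            if open_trial is None:
                raise TrialStructureError(
                    f"outcome {ev!r} at t={row.timestamp_s:.3f} s has no "
                    f"preceding stimulus onset")
            t_out = float(row.timestamp_s)
            open_trial.update(
                outcome=ev, outcome_time=t_out,
                response_latency=(t_out - open_trial["onset"]
                                  if ev in ("hit", "false_alarm") else np.nan),
                reward_latency=np.nan)
            rows.append(open_trial)
            pending_hit = open_trial if ev == "hit" else None
            open_trial = None
        elif ev == "tray_entry" and pending_hit is not None:
            pending_hit["reward_latency"] = (
                float(row.timestamp_s) - pending_hit["outcome_time"])
            pending_hit = None
    if open_trial is not None:
        raise TrialStructureError(
            f"stimulus at t={open_trial['onset']:.3f} s has no outcome "
            f"before the end of the log")
    cols = ["trial_id", "stimulus", "onset", "outcome", "outcome_time",
            "is_correction", "response_latency", "reward_latency"]
    df = pd.DataFrame(rows, columns=cols)
    df["trial_id"] = df["trial_id"].astype("Int64")
    lh = schedule.limited_hold
    too_long = df["outcome_time"] > df["onset"] + lh + 1e-6
    if too_long.any():
        t = df.loc[too_long, "onset"].iloc[0]
        raise TrialStructureError(
            f"trial at t={t:.3f} s: outcome later than onset + limited hold "
            f"({lh} s)")
    return df


def orient_trials(trials: pd.DataFrame, frame_classes: pd.DataFrame,
                  frame_rate: float | None = None) -> pd.DataFrame:
    """Join per-frame classes into per-trial orientation flags.

    ``frame_classes`` is the per-frame table from
    :func:`rcptvfa.visual_field.classify_track` (``frame_class`` in
    {oriented, blind, excluded, invalid}); frame times are taken from its
    ``time`` column, or derived from ``frame_index`` when ``frame_rate`` is
    given.  A trial is oriented when >= 1 valid frame in [onset, outcome)
    is oriented; with zero valid frames the flag is indeterminate (NA).
    """
    times = frame_classes["time"].to_numpy(float)
    if frame_rate is not None:
        times = frame_classes["frame_index"].to_numpy(float) / float(frame_rate)
    classes = frame_classes["frame_class"].to_numpy()
    order = np.argsort(times, kind="stable")
    times, classes = times[order], classes[order]
    valid = (classes == "oriented") | (classes == "blind")
    oriented = classes == "oriented"
    cum_valid = np.concatenate([[0], np.cumsum(valid)])
    cum_orient = np.concatenate([[0], np.cumsum(oriented)])

    onsets = trials["onset"].to_numpy(float)
    outs = trials["outcome_time"].to_numpy(float)
    i0 = np.searchsorted(times, onsets, side="left")
    i1 = np.searchsorted(times, outs, side="left")  # half-open at the outcome
    n_frames = i1 - i0
    n_valid = cum_valid[i1] - cum_valid[i0]
    n_orient = cum_orient[i1] - cum_orient[i0]
    if (n_frames == 0).any():
        log.warning("%d trials contain no video frames at all",
                    int((n_frames == 0).sum()))

    flag = pd.array([pd.NA] * len(trials), dtype="boolean")
    determinate = n_valid > 0
    flag[determinate] = (n_orient[determinate] >= 1)
    return pd.DataFrame({
        "trial_id": trials["trial_id"].to_numpy(),
        "n_frames_in_window": n_frames,
        "n_valid_frames": n_valid,
        "n_oriented_frames": n_orient,
        "oriented": flag,
    })


def orientation_index(trial_orient: pd.DataFrame, trials: pd.DataFrame,
                      bins: BinSpec, by_response_type: bool = False,
                      include_correction: bool = False) -> pd.DataFrame:
    """Oriented trials / total trials, per time bin.

    Indeterminate trials are dropped from numerator and denominator (their
    count is reported); empty bins report a missing index, never 0.  When
    ``by_response_type`` is set, indices are added per outcome.
    """
    df = trials.merge(trial_orient[["trial_id", "oriented"]], on="trial_id")
    if not include_correction:
        df = df[~df["is_correction"]]
    df = df.assign(bin_index=bins.assign(df["onset"]))

    out = []
    for b in range(bins.n_bins):
        sub = df[df["bin_index"] == b]
        det = sub[sub["oriented"].notna()]
        row = {
            "bin_index": b,
            "n_trials": len(sub),
            "n_indeterminate": int(sub["oriented"].isna().sum()),
            "n_oriented": int(det["oriented"].sum()),
            "orientation_index": (float(det["oriented"].mean())
                                  if len(det) else np.nan),
        }
        if by_response_type:
            for oc in OUTCOME_EVENTS:
                d = det[det["outcome"] == oc]
                row[f"orientation_index_{oc}"] = (
                    float(d["oriented"].mean()) if len(d) else np.nan)
        out.append(row)
    return pd.DataFrame(out)
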