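"""Discrete-event simulation of rodent Continuous Performance Test sessions.

The simulator plays a single agent through one touchscreen session and emits
an ABET-style event log plus ground truth for every stochastic draw.  The
task is a go/no-go discrimination: on each trial a target (S+) or non-target
(S-) appears for the stimulus duration and the animal may touch it during
the limited hold (stimulus duration + a short post-stimulus interval).
Touch/no-touch crossed with S+/S- gives the four outcomes hit, miss,
false alarm and correct rejection.  Hits deliver a liquid reward collected
at the tray; false alarms trigger correction trials (the non-target repeats
until the agent withholds).  Touches during the inter-trial interval (ITI)
restart it and index impulsivity.

The agent is the simplest generative family able to produce a time-on-task
decrement: per-trial Bernoulli outcomes whose propensities drift linearly
with session time, log-normal response/reward latencies, a Bernoulli
screen-orientation policy (with its own drift), and Poisson ITI touching.

RNG draw order per trial is part of the module contract (tests replay it):
stimulus class, outcome, orientation, [response latency], [reward latency],
then ITI exponential gaps; correction trials consume outcome, orientation,
[latency] and ITI gaps inline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EVENT_TYPES = (
    "session_start",
    "stim_on_splus",
    "stim_on_sminus",
    "hit",
    "miss",
    "false_alarm",
    "correct_rejection",
    "correction_stim_on",
    "iti_touch",
    "reward_delivered",
    "tray_entry",
    "session_end",
)

OUTCOME_EVENTS = ("hit", "miss", "false_alarm", "correct_rejection")


class ConfigurationError(ValueError):
    """A schedule/agent/layout field is out of its valid domain."""


@dataclass(frozen=True)
class SessionSchedule:
    """Task parameters of one session stage.

    ``limited_hold`` is derived: stimulus duration plus the post-stimulus
    interval during which a touch still counts (0.5 s in all stages).
    """

    stage: str
    session_duration: float
    stimulus_duration: float
    iti_duration: float
    s_plus_probability: float
    reward_cap: int
    post_stimulus_interval: float = 0.5
    reward_volume_ul: float = 20.0
    correction_trials_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("session_duration", "stimulus_duration", "iti_duration",
                     "post_stimulus_interval", "reward_volume_ul"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v!r}")
        if self.session_duration <= 0:
            raise ConfigurationError("session_duration must be > 0")
        if not 0.0 <= self.s_plus_probability <= 1.0:
            raise ConfigurationError(
                f"s_plus_probability must be in [0, 1], got {self.s_plus_probability!r}")
        if self.reward_cap < 1:
            raise ConfigurationError("reward_cap must be >= 1")

    @property
    def limited_hold(self) -> float:
        return self.stimulus_duration + self.post_stimulus_interval


def stage1_schedule(**overrides) -> SessionSchedule:
    """Stage 1: 10 s white square, 2 s ITI, every trial rewarded on touch."""
    base = dict(stage="1", session_duration=45 * 60.0, stimulus_duration=10.0,
                iti_duration=2.0, s_plus_probability=1.0, reward_cap=150,
                correction_trials_enabled=False)
    base.update(overrides)
    return SessionSchedule(**base)


def stage2_schedule(**overrides) -> SessionSchedule:
    """Stage 2: target stimulus replaces the square, SD reduced to 5 s."""
    base = dict(stage="2", session_duration=45 * 60.0, stimulus_duration=5.0,
                iti_duration=2.0, s_plus_probability=1.0, reward_cap=150,
                correction_trials_enabled=False)
    base.update(overrides)
    return SessionSchedule(**base)


def stage3_schedule(**overrides) -> SessionSchedule:
    """Stage 3: S+/S- at 50%, SD 3 s (limited hold 3.5 s), ITI 5 s, 45 min."""
    base = dict(stage="3", session_duration=45 * 60.0, stimulus_duration=3.0,
                iti_duration=5.0, s_plus_probability=0.5, reward_cap=150,
                correction_trials_enabled=True)
    base.update(overrides)
    return SessionSchedule(**base)


def tot_probe_schedule(**overrides) -> SessionSchedule:
    """Time-on-task probe: Stage 3 extended to 90 min, reward cap 999."""
    base = dict(stage="tot_probe", session_duration=90 * 60.0,
                stimulus_duration=3.0, iti_duration=5.0, s_plus_probability=0.5,
                reward_cap=999, correction_trials_enabled=True)
    base.update(overrides)
    return SessionSchedule(**base)


SCHEDULE_PRESETS = {
    "stage1": stage1_schedule,
    "stage2": stage2_schedule,
    "stage3": stage3_schedule,
    "tot_probe": tot_probe_schedule,
}


@dataclass(frozen=True)
class AgentParams:
    """Generative behavioural parameters of the simulated animal.

    Propensities are per-trial Bernoulli probabilities evaluated at the
    trial's onset; ``*_drift`` terms are additive per-minute slopes and the
    drifted value is clamped to [0, 1].  Latency distributions are
    log-normal, parameterised by the log-scale mean ``mu`` (so the median is
    exp(mu) seconds) and log-scale ``sigma``.  Response latencies are
    resampled until they fall inside the limited hold.

    Defaults emulate a trained male mouse in a time-on-task probe: hit
    propensity declining with time on task, mildly declining false-alarm
    propensity, and a high, stable screen-orientation policy.
    """

    hit_propensity_0: float = 0.65
    fa_propensity_0: float = 0.25
    hit_drift: float = -0.003       # per minute
    fa_drift: float = -0.001        # per minute
    orientation_p0: float = 0.92
    orientation_drift: float = 0.0  # per minute
    correct_latency_mu: float = 0.2     # median ~1.22 s
    correct_latency_sigma: float = 0.35
    incorrect_latency_mu: float = 0.1   # median ~1.11 s
    incorrect_latency_sigma: float = 0.35
    reward_latency_mu: float = 0.0      # median 1.0 s
    reward_latency_sigma: float = 0.45
    iti_touch_rate: float = 0.02    # touches / s during ITI
    iti_touch_drift: float = 0.0    # per minute
    correction_loop_cap: int = 25

    def __post_init__(self) -> None:
        for name in ("hit_propensity_0", "fa_propensity_0", "orientation_p0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("correct_latency_sigma", "incorrect_latency_sigma",
                     "reward_latency_sigma"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.iti_touch_rate < 0:
            raise ConfigurationError("iti_touch_rate must be >= 0")
        if self.correction_loop_cap < 1:
            raise ConfigurationError("correction_loop_cap must be >= 1")

    def hit_propensity(self, t: float) -> float:
        return _clamp01(self.hit_propensity_0 + self.hit_drift * t / 60.0)

    def fa_propensity(self, t: float) -> float:
        return _clamp01(self.fa_propensity_0 + self.fa_drift * t / 60.0)

    def orientation_p(self, t: float) -> float:
        return _clamp01(self.orientation_p0 + self.orientation_drift * t / 60.0)

    def iti_rate(self, t: float) -> float:
        return max(0.0, self.iti_touch_rate + self.iti_touch_drift * t / 60.0)


def _clamp01(p: float) -> float:
    if p < 0.0 or p > 1.0:
        log.debug("propensity %.4f outside [0, 1]; clamped", p)
    return min(1.0, max(0.0, p))


@dataclass
class GroundTruth:
    """Every stochastic draw of a simulated session, for downstream checks.

    ``trials`` has one row per trial (corrections included) with the
    stimulus, outcome, times, latencies and the orientation policy draw
    (``oriented_intent``).  ``frames`` is populated by pose synthesis with
    the realised per-frame oriented flag and the injected artifact label;
    pose synthesis also sets the realised per-trial ``oriented`` flag so
    that trial flags always equal the OR over limited-hold frame flags.
    ``bins`` holds the true (drifted) propensities at bin midpoints.
    """

    trials: pd.DataFrame
    bins: pd.DataFrame
    frames: pd.DataFrame | None = None
    end_reason: str = "clock"
    n_rewards: int = 0
    n_iti_episodes: int = 0
    n_iti_touches: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def total_reward_volume_ul(self) -> float:
        return self.n_rewards * self.extra.get("reward_volume_ul", 20.0)


def true_bin_propensities(schedule: SessionSchedule, agent: AgentParams,
                          bin_width: float = 900.0) -> pd.DataFrame:
    n_bins = int(math.ceil(schedule.session_duration / bin_width))
    mids = (np.arange(n_bins) + 0.5) * bin_width
    return pd.DataFrame({
        "bin_index": np.arange(n_bins),
        "t_mid": mids,
        "hit_propensity": [agent.hit_propensity(t) for t in mids],
        "fa_propensity": [agent.fa_propensity(t) for t in mids],
        "orientation_p": [agent.orientation_p(t) for t in mids],
    })


class _EventLog:
    def __init__(self) -> None:
        self.rows: list[tuple[float, str, object, bool]] = []

    def add(self, t: float, event: str, trial_id=None, is_correction=False) -> None:
        self.rows.append((t, event, trial_id, bool(is_correction)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows,
                          columns=["timestamp_s", "event", "trial_id", "is_correction"])
        df["trial_id"] = df["trial_id"].astype("Int64")
        return df


def simulate_session(schedule: SessionSchedule, agent: AgentParams,
                     seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Run one session; return the event log and its ground truth.

    The session terminates at the earlier of the session clock and the
    reward cap (checked at trial boundaries; a trial in progress when the
    clock expires is completed, as the chamber software would).
    """
    rng = np.random.default_rng(seed)
    ev = _EventLog()
    ev.add(0.0, "session_start")

    t = 0.0
    trial_id = 0
    rewards = 0
    iti_episodes = 0
    iti_touches = 0
    trows: list[dict] = []
    end_reason = "clock"

    def run_iti(t0: float) -> float:
        nonlocal iti_episodes, iti_touches
        iti_episodes += 1
        rate = agent.iti_rate(t0)
        tt = t0
        while True:
            gap = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            if gap >= schedule.iti_duration:
                return tt + schedule.iti_duration
            tt += gap
            ev.add(tt, "iti_touch")
            iti_touches += 1
            iti_episodes += 1  # a touch restarts the ITI: a new initiation

    def draw_latency(mu: float, sigma: float, cap: float | None) -> float:
        for _ in range(64):
            lat = float(rng.lognormal(mu, sigma))
            if cap is None or lat < cap:
                return lat
        return 0.99 * cap if cap is not None else lat

    def run_trial(t_on: float, tid: int, is_corr: bool,
                  splus: bool) -> tuple[float, dict]:
        """Play one stimulus presentation; return (time after outcome, record)."""
        nonlocal rewards
        stim_event = ("correction_stim_on" if is_corr
                      else ("stim_on_splus" if splus else "stim_on_sminus"))
        ev.add(t_on, stim_event, tid, is_corr)
        p = agent.hit_propensity(t_on) if splus else agent.fa_propensity(t_on)
        respond = bool(rng.random() < p)
        oriented = bool(rng.random() < agent.orientation_p(t_on))
        rec = dict(trial_id=tid, is_correction=is_corr,
                   stimulus="S+" if splus else "S-", onset=t_on,
                   oriented_intent=oriented, propensity=p,
                   response_latency=np.nan, reward_latency=np.nan)
        if respond:
            lat = draw_latency(
                agent.correct_latency_mu if splus else agent.incorrect_latency_mu,
                agent.correct_latency_sigma if splus else agent.incorrect_latency_sigma,
                schedule.limited_hold)
            t_out = t_on + lat
            outcome = "hit" if splus else "false_alarm"
            rec["response_latency"] = lat
        else:
            t_out = t_on + schedule.limited_hold
            outcome = "miss" if splus else "correct_rejection"
        ev.add(t_out, outcome, tid, is_corr)
        rec.update(outcome=outcome, outcome_time=t_out)
        t_next = t_out
        if outcome == "hit":
            ev.add(t_out, "reward_delivered", tid, is_corr)
            rewards += 1
            rlat = draw_latency(agent.reward_latency_mu,
                                agent.reward_latency_sigma, None)
            rec["reward_latency"] = rlat
            ev.add(t_out + rlat, "tray_entry", tid, is_corr)
            t_next = t_out + rlat
        return t_next, rec

    while t < schedule.session_duration and rewards < schedule.reward_cap:
        trial_id += 1
        splus = bool(rng.random() < schedule.s_plus_probability)
        t, rec = run_trial(t, trial_id, False, splus)
        trows.append(rec)
        t = run_iti(t)
        if rec["outcome"] == "false_alarm" and schedule.correction_trials_enabled:
            for k in range(agent.correction_loop_cap):
                trial_id += 1
                t, crec = run_trial(t, trial_id, True, False)
                trows.append(crec)
                t = run_iti(t)
                if crec["outcome"] == "correct_rejection":
                    break
            else:
                log.warning("correction loop hit cap %d at t=%.1f s; forced exit",
                            agent.correction_loop_cap, t)
        if rewards >= schedule.reward_cap:
            end_reason = "reward_cap"

    t_end = max(t, schedule.session_duration) if end_reason == "clock" else t
    ev.add(t_end, "session_end")

    trials = pd.DataFrame(trows)
    if trials.empty:
        trials = pd.DataFrame(columns=[
            "trial_id", "is_correction", "stimulus", "onset", "oriented_intent",
            "propensity", "response_latency", "reward_latency", "outcome",
            "outcome_time"])
    trials["oriented"] = trials.get("oriented_intent", pd.Series(dtype=bool))

    truth = GroundTruth(
        trials=trials,
        bins=true_bin_propensities(schedule, agent),
        end_reason=end_reason,
        n_rewards=rewards,
        n_iti_episodes=iti_episodes,
        n_iti_touches=iti_touches,
        extra={"reward_volume_ul": schedule.reward_volume_ul,
               "session_duration": schedule.session_duration,
               "t_end": t_end, "seed": seed,
               "limited_hold": schedule.limited_hold},
    )
    return ev.to_frame(), truth


def check_event_invariants(events: pd.DataFrame,
                           correction_enabled: bool = True) -> None:
    """Raise AssertionError if the event log violates its structural contract.

    Checks: non-decreasing timestamps; exactly one outcome per trial_id;
    every hit followed by one reward_delivered and one tray_entry before the
    next stimulus onset; every non-correction false alarm (with corrections
    enabled) followed by >= 1 correction_stim_on before the next
    non-correction trial.
    """
    ts = events["timestamp_s"].to_numpy()
    assert np.all(np.diff(ts) >= 0), "timestamps must be non-decreasing"

    outcomes = events[events["event"].isin(OUTCOME_EVENTS)]
    per_trial = outcomes.groupby("trial_id").size()
    assert (per_trial == 1).all(), "each trial_id must have exactly one outcome"

    stim_events = {"stim_on_splus", "stim_on_sminus", "correction_stim_on"}
    n_stim = events["event"].isin(stim_events).sum()
    assert n_stim == len(outcomes), "each stimulus onset must pair with one outcome"

    seq = list(events.itertuples(index=False))
    for i, row in enumerate(seq):
        if row.event == "hit":
            rewards = trays = 0
            for nxt in seq[i + 1:]:
                if nxt.event in stim_events:
                    break
                rewards += nxt.event == "reward_delivered"
                trays += nxt.event == "tray_entry"
            assert rewards == 1 and trays == 1, (
                f"hit at t={row.timestamp_s} lacks reward/tray before next stimulus")
        if row.event == "false_alarm" and not row.is_correction and correction_enabled:
            saw_correction = False
            for nxt in seq[i + 1:]:
                if nxt.event in ("stim_on_splus", "stim_on_sminus"):
                    break
                if nxt.event == "correction_stim_on":
                    saw_correction = True
                    break
            assert saw_correction, (
                f"false alarm at t={row.timestamp_s} not followed by a correction trial")
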