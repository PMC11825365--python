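"""Synthesis of DeepLabCut-style keypoint tracks for a simulated session.

Given a simulated event log and its ground truth, this module renders one
pose frame per video frame: three keypoints (top of the head / nose, left
ear, right ear) with per-keypoint likelihoods, in the image frame of the
top-down camera.  Outside limited-hold windows the head position follows an
Ornstein-Uhlenbeck walk around the arena centre and the heading an OU walk
around the direction facing away from the screen.  During the limited hold
of a trial drawn "oriented" the gaze is aimed at the stimulus segment's
midpoint; during a non-oriented trial's limited hold it points directly
away, which (with the head kept in the central arena region) guarantees the
whole segment lies deep in the blind sector.

Measurement artifacts are injected per frame with the requested rates:
Gaussian jitter on every coordinate, "outlier" frames where one keypoint
jumps far from the head, and "low-likelihood" frames where one keypoint's
likelihood drops below the QC cutoff.  Artifact categories are mutually
exclusive, so the ground-truth frame labels partition the track.

Ground-truth per-frame oriented/blind labels are computed with an exact
interval construction (linear root solves at the +/- lateral boundary),
not the sampling-based classifier used by the analysis stages, so the two
routes stay independent.  After labelling, each trial's realised oriented
flag is reset to the OR over its limited-hold frames' labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .chamber import BODYPARTS, ChamberLayout, LayoutError
from .simulate import GroundTruth

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["frame_index", "time"] + [
    f"{bp}_{c}" for bp in BODYPARTS for c in ("x", "y", "likelihood")]

ARTIFACT_LABELS = ("clean", "outlier", "low_likelihood")


@dataclass(frozen=True)
class PoseNoise:
    """Per-frame artifact rates for the synthetic keypoint track."""

    jitter_px: float = 1.0
    outlier_rate: float = 0.02
    low_likelihood_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        for name in ("outlier_rate", "low_likelihood_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.outlier_rate + self.low_likelihood_rate > 1.0:
            raise ValueError("artifact rates must sum to <= 1")


def exact_blind_fraction(origins: np.ndarray, bearings_deg: np.ndarray,
                         segment, lateral_bound: float = 103.4) -> np.ndarray:
    """Exact fraction of the segment beyond the lateral bound (blind sector).

    The signed bearing to a point of the segment is a continuous function of
    the segment parameter s except at +/-180 deg (where it stays blind), so
    the blind indicator switches only where |bearing| crosses the lateral
    bound.  Those crossings satisfy a linear equation in s (the point lies
    on the boundary ray), giving at most one root per boundary; sector
    membership on each subinterval is read off at its midpoint and the blind
    fraction is the summed parameter length.
    """
    o = np.atleast_2d(np.asarray(origins, float))
    b = np.radians(np.asarray(bearings_deg, float).ravel())
    seg = np.asarray(segment, float)
    a, d = seg[0], seg[1] - seg[0]
    n = len(o)
    gx, gy = np.cos(b), np.sin(b)
    wx, wy = a[0] - o[:, 0], a[1] - o[:, 1]

    roots = np.full((n, 2), 1.0)
    for j, alpha in enumerate((lateral_bound, -lateral_bound)):
        ca, sa = np.cos(np.radians(alpha)), np.sin(np.radians(alpha))
        rx, ry = gx * ca - gy * sa, gx * sa + gy * ca
        c0 = rx * wy - ry * wx
        c1 = rx * d[1] - ry * d[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -c0 / c1
        vx, vy = wx + s * d[0], wy + s * d[1]
        ok = np.isfinite(s) & (s > 0.0) & (s < 1.0) & (rx * vx + ry * vy > 0.0)
        roots[ok, j] = s[ok]
    roots.sort(axis=1)

    edges = np.column_stack([np.zeros(n), roots, np.ones(n)])
    frac = np.zeros(n)
    for k in range(3):
        mid = 0.5 * (edges[:, k] + edges[:, k + 1])
        length = edges[:, k + 1] - edges[:, k]
        vx, vy = wx + mid * d[0], wy + mid * d[1]
        theta = np.abs(np.degrees(np.arctan2(gx * vy - gy * vx, gx * vx + gy * vy)))
        frac += length * (theta > lateral_bound)
    return frac


def _ou_series(rng: np.random.Generator, n: int, tau_frames: float,
               sigma: float) -> np.ndarray:
    """Zero-mean OU path via an AR(1) recursion (stationary start)."""
    phi = np.exp(-1.0 / tau_frames)
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    e = rng.normal(0.0, innov_sd, n)
    e[0] = rng.normal(0.0, sigma)
    return lfilter([1.0], [1.0, -phi], e)


def synthesize_pose(events: pd.DataFrame, truth: GroundTruth,
                    layout: ChamberLayout, noise: PoseNoise,
                    seed: int, lateral_bound: float = 103.4,
                    blind_threshold: float = 0.90,
                    ear_half_span_px: float = 12.0,
                    nose_length_px: float = 17.0) -> pd.DataFrame:
    """Render the keypoint track for a session; updates ``truth`` in place.

    Returns a DataFrame with one row per video frame and columns
    ``frame_index, time`` plus ``{bodypart}_{x,y,likelihood}`` for the three
    body parts.  ``truth.frames`` gains per-frame oriented flags and
    artifact labels; ``truth.trials['oriented']`` is reset to the realised
    OR-over-window flags.
    """
    if not (layout.frame_rate > 0 and np.isfinite(layout.frame_rate)):
        raise LayoutError("frame_rate must be positive and finite")
    t_end = float(events.loc[events["event"] == "session_end", "timestamp_s"].iloc[-1])
    n = int(round(layout.frame_rate * t_end))
    if n <= 0:
        raise LayoutError("session too short for a single video frame")
    rng = np.random.default_rng(seed)
    times = np.arange(n) / layout.frame_rate

    # Head position: OU walk around the arena centroid, clamped to a central
    # box kept well away from the screen wall so away-facing headings always
    # leave the whole stimulus segment deep in the blind sector.
    centre = layout.arena_centroid
    px = centre[0] + _ou_series(rng, n, tau_frames=4.0 * layout.frame_rate, sigma=45.0)
    py = centre[1] + _ou_series(rng, n, tau_frames=4.0 * layout.frame_rate, sigma=35.0)
    seg = np.asarray(layout.stimulus_segment, float)
    seg_mid = seg.mean(axis=0)
    seg_span = np.linalg.norm(seg[1] - seg[0])
    min_standoff = 1.5 * seg_span
    away = centre - seg_mid
    px = np.clip(px, centre[0] - 150.0, centre[0] + 150.0)
    # keep the head at least 1.5 segment-lengths from the screen (along the
    # centroid->segment axis this is approximately the y clamp below)
    lo = seg_mid[1] + min_standoff if away[1] > 0 else centre[1] - 120.0
    hi = centre[1] + 120.0 if away[1] > 0 else seg_mid[1] - min_standoff
    py = np.clip(py, lo, hi)
    pos = np.column_stack([px, py])

    to_mid = seg_mid[None, :] - pos
    bearing_to_mid = np.degrees(np.arctan2(to_mid[:, 1], to_mid[:, 0]))
    heading = bearing_to_mid + 180.0 + _ou_series(
        rng, n, tau_frames=2.0 * layout.frame_rate, sigma=40.0)

    # Limited-hold overrides from the ground-truth trial table
    trials = truth.trials
    frame_trial = np.full(n, -1, dtype=np.int64)
    for row in trials.itertuples(index=False):
        i0 = int(np.ceil(row.onset * layout.frame_rate))
        i1 = int(np.ceil(row.outcome_time * layout.frame_rate))  # [onset, outcome)
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        frame_trial[i0:i1] = row.trial_id
        if row.oriented_intent:
            heading[i0:i1] = bearing_to_mid[i0:i1]
        else:
            heading[i0:i1] = bearing_to_mid[i0:i1] + 180.0

    # Render keypoints and apply coordinate jitter
    h = np.radians(heading)
    fwd = np.column_stack([np.cos(h), np.sin(h)])
    left = np.column_stack([-np.sin(h), np.cos(h)])  # cross(fwd, left) = +1
    nose = pos + nose_length_px * fwd
    lear = pos + ear_half_span_px * left
    rear = pos - ear_half_span_px * left
    if noise.jitter_px > 0:
        nose += rng.normal(0.0, noise.jitter_px, (n, 2))
        lear += rng.normal(0.0, noise.jitter_px, (n, 2))
        rear += rng.normal(0.0, noise.jitter_px, (n, 2))

    # Ground-truth frame labels from the jittered (pre-artifact) keypoints
    origin = 0.5 * (lear + rear)
    dvec = nose - origin
    true_bearing = np.degrees(np.arctan2(dvec[:, 1], dvec[:, 0]))
    blind_frac = exact_blind_fraction(origin, true_bearing,
                                      layout.stimulus_segment, lateral_bound)
    frame_oriented = blind_frac < blind_threshold

    # Artifact injection: mutually exclusive per-frame labels
    u = rng.random(n)
    artifact = np.where(u < noise.outlier_rate, "outlier",
                        np.where(u < noise.outlier_rate + noise.low_likelihood_rate,
                                 "low_likelihood", "clean"))
    lik = rng.uniform(0.95, 1.0, (n, 3))
    which = rng.integers(0, 3, n)
    xyz = [nose, lear, rear]
    out_idx = np.flatnonzero(artifact == "outlier")
    if out_idx.size:
        ang = rng.uniform(0.0, 2 * np.pi, out_idx.size)
        dist = rng.uniform(150.0, 250.0, out_idx.size)
        for j, i in enumerate(out_idx):
            xyz[which[i]][i] += dist[j] * np.array([np.cos(ang[j]), np.sin(ang[j])])
    low_idx = np.flatnonzero(artifact == "low_likelihood")
    if low_idx.size:
        lik[low_idx, which[low_idx]] = rng.uniform(0.2, 0.85, low_idx.size)

    track = pd.DataFrame({
        "frame_index": np.arange(n), "time": times,
        "head_top_x": nose[:, 0], "head_top_y": nose[:, 1],
        "head_top_likelihood": lik[:, 0],
        "left_ear_x": lear[:, 0], "left_ear_y": lear[:, 1],
        "left_ear_likelihood": lik[:, 1],
        "right_ear_x": rear[:, 0], "right_ear_y": rear[:, 1],
        "right_ear_likelihood": lik[:, 2],
    })

    truth.frames = pd.DataFrame({
        "frame_index": np.arange(n), "time": times,
        "oriented": frame_oriented, "artifact": artifact,
        "trial_id": pd.array(np.where(frame_trial >= 0, frame_trial, pd.NA),
                             dtype="Int64"),
    })

    # Realised per-trial flags: OR over limited-hold frame labels
    in_window = truth.frames["trial_id"].notna()
    realised = truth.frames[in_window].groupby("trial_id")["oriented"].any()
    trials = trials.set_index("trial_id")
    trials["oriented"] = pd.array([pd.NA] * len(trials), dtype="boolean")
    trials.loc[realised.index, "oriented"] = realised.to_numpy()
    truth.trials = trials.reset_index()
    return track
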