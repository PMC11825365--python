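"""Head-centred visual-field geometry from three keypoints.

A mouse's head pose in the top-down camera view is reduced to an origin (the
midpoint of the two ears) and a gaze bearing (the direction from that origin
to the nose/top-of-head keypoint).  Bearings around the gaze axis are
partitioned into sectors: frontal (binocular overlap, default half-width
20 deg), lateral left/right (monocular, out to a default 103.4 deg
half-width of total coverage per side), and blind beyond that.  The
touchscreen stimulus window is a 1-D segment in this view (the screen is a
wall); the fraction of the segment subtended by each sector is estimated by
discretising the segment into equally spaced sample points and binning each
point's absolute signed bearing.

Conventions (image frame): origin top-left, x right, y down, units pixels.
Bearings are degrees in (-180, 180] from the +x axis.  The signed bearing
from the gaze axis to a point is positive on the animal's LEFT, defined as
the counter-clockwise sense of atan2(cross, dot) in image coordinates.

A frame is "blind" when at least 90% of the stimulus segment falls in the
blind sector, otherwise "oriented".  Sector bounds are inclusive on the
seeing side (theta <= frontal bound is frontal, theta <= lateral bound is
lateral), so the blind sector is open; the blind-rule threshold itself is
inclusive (>= 0.90).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chamber import ChamberLayout

log = logging.getLogger(__name__)

_EPS_POSE = 1e-6  # px: nose this close to the ear midpoint -> pose invalid

FRACTION_COLUMNS = ("frontal", "lateral_left", "lateral_right", "blind",
                    "left_all", "right_all")


@dataclass(frozen=True)
class FieldAngles:
    """Sector bounds in degrees from the gaze axis.

    By default the configured values are HALF-widths: ``frontal_half_angle``
    20 gives a 40 deg binocular sector, and ``lateral_bound`` 103.4 means
    total visual coverage of 103.4 deg per side, beyond which is blind.  Set
    ``values_are_half_widths=False`` to interpret supplied full-widths
    (they are halved on access).
    """

    frontal_half_angle: float = 20.0
    lateral_bound: float = 103.4
    values_are_half_widths: bool = True

    def __post_init__(self) -> None:
        f, lb = self._resolve()
        if not 0.0 < f < lb <= 180.0:
            raise ValueError(
                f"need 0 < frontal ({f}) < lateral bound ({lb}) <= 180")

    def _resolve(self) -> tuple[float, float]:
        if self.values_are_half_widths:
            return self.frontal_half_angle, self.lateral_bound
        return self.frontal_half_angle / 2.0, self.lateral_bound / 2.0

    @property
    def frontal(self) -> float:
        return self._resolve()[0]

    @property
    def lateral(self) -> float:
        return self._resolve()[1]


@dataclass(frozen=True)
class ClassifierParams:
    blind_threshold: float = 0.90
    segment_samples: int = 201

    def __post_init__(self) -> None:
        if not 0.0 < self.blind_threshold <= 1.0:
            raise ValueError("blind_threshold must be in (0, 1]")
        if self.segment_samples < 2:
            raise ValueError("segment_samples must be >= 2")


def normalize_angle_deg(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def estimate_head_pose(track: pd.DataFrame) -> pd.DataFrame:
    """Head origin and gaze bearing for every frame of a keypoint track.

    Returns a DataFrame indexed like ``track`` with columns ``origin_x``,
    ``origin_y``, ``bearing_deg`` and ``valid``; a pose is invalid when the
    nose keypoint coincides with the ear midpoint (within 1e-6 px) or any
    coordinate is non-finite.
    """
    nose = track[["head_top_x", "head_top_y"]].to_numpy(float)
    le = track[["left_ear_x", "left_ear_y"]].to_numpy(float)
    re = track[["right_ear_x", "right_ear_y"]].to_numpy(float)
    origin = 0.5 * (le + re)
    d = nose - origin
    norm = np.hypot(d[:, 0], d[:, 1])
    finite = np.isfinite(nose).all(axis=1) & np.isfinite(le).all(axis=1) \
        & np.isfinite(re).all(axis=1)
    valid = finite & (norm > _EPS_POSE)
    with np.errstate(invalid="ignore"):
        bearing = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    bearing = normalize_angle_deg(bearing)
    bearing[~valid] = np.nan
    return pd.DataFrame({
        "origin_x": origin[:, 0], "origin_y": origin[:, 1],
        "bearing_deg": bearing, "valid": valid,
    }, index=track.index)


def signed_bearing_to_point(origin, bearing_deg: float, p) -> float:
    """Signed angle (deg, (-180, 180]) from the gaze axis to origin->p.

    Positive on the animal's left.  Undefined (ValueError) when ``p`` equals
    the origin.
    """
    ox, oy = float(origin[0]), float(origin[1])
    vx, vy = float(p[0]) - ox, float(p[1]) - oy
    if vx * vx + vy * vy == 0.0:
        raise ValueError("bearing to the pose origin itself is undefined")
    b = math.radians(bearing_deg)
    gx, gy = math.cos(b), math.sin(b)
    theta = math.degrees(math.atan2(gx * vy - gy * vx, gx * vx + gy * vy))
    return float(normalize_angle_deg(theta))


def _segment_points(segment, n: int) -> np.ndarray:
    """Midpoints of n equal subintervals: equally spaced, and the count/n
    estimate of a sector's parameter length errs by at most 0.5/n per
    sector-boundary crossing (at most two crossings per sector)."""
    a = np.asarray(segment[0], float)
    b = np.asarray(segment[1], float)
    if np.allclose(a, b):
        raise ValueError("stimulus segment endpoints must be distinct")
    s = (np.arange(n) + 0.5) / n
    return a[None, :] + s[:, None] * (b - a)[None, :]


def stimulus_field_fractions(origin, bearing_deg: float, segment,
                             angles: FieldAngles = FieldAngles(),
                             params: ClassifierParams = ClassifierParams(),
                             ) -> dict[str, float]:
    """Fractions of the stimulus segment in each visual-field sector.

    The segment is discretised into ``params.segment_samples`` equally
    spaced points; each point's absolute signed bearing assigns it to
    frontal, lateral left/right or blind.  ``left_all``/``right_all`` add
    the frontal samples on each side (on-axis samples split evenly), so
    left_all + right_all = 1 - blind.  A sample coinciding with the pose
    origin is dropped and the fractions renormalised.
    """
    out = stimulus_field_fractions_track(
        np.asarray([origin], float), np.asarray([bearing_deg], float),
        segment, angles, params)
    return {k: float(out[k][0]) for k in FRACTION_COLUMNS}


def stimulus_field_fractions_track(origins: np.ndarray, bearings_deg: np.ndarray,
                                   segment, angles: FieldAngles,
                                   params: ClassifierParams,
                                   chunk: int = 20000) -> dict[str, np.ndarray]:
    """Vectorised :func:`stimulus_field_fractions` over many frames."""
    pts = _segment_points(segment, params.segment_samples)  # (S, 2)
    n = len(origins)
    res = {k: np.empty(n) for k in FRACTION_COLUMNS}
    f_bound, l_bound = angles.frontal, angles.lateral
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        o = origins[lo:hi]
        b = np.radians(bearings_deg[lo:hi])
        gx, gy = np.cos(b)[:, None], np.sin(b)[:, None]
        vx = pts[None, :, 0] - o[:, 0:1]
        vy = pts[None, :, 1] - o[:, 1:2]
        dot = gx * vx + gy * vy
        cross = gx * vy - gy * vx
        theta = np.degrees(np.arctan2(cross, dot))  # (n, S)
        degenerate = (vx == 0) & (vy == 0)
        if degenerate.any():
            log.warning("pose origin lies on the stimulus segment in %d frames; "
                        "those samples dropped", int(degenerate.any(axis=1).sum()))
        ok = ~degenerate
        counts = ok.sum(axis=1).astype(float)
        counts[counts == 0] = np.nan
        at = np.abs(theta)
        frontal = ok & (at <= f_bound)
        lateral = ok & (at > f_bound) & (at <= l_bound)
        blind = ok & (at > l_bound)
        left = theta > 0
        right = theta < 0
        on_axis = ok & (theta == 0.0)
        res["frontal"][lo:hi] = frontal.sum(axis=1) / counts
        res["lateral_left"][lo:hi] = (lateral & left).sum(axis=1) / counts
        res["lateral_right"][lo:hi] = (lateral & right).sum(axis=1) / counts
        res["blind"][lo:hi] = blind.sum(axis=1) / counts
        seeing_left = ((frontal | lateral) & left).sum(axis=1) \
            + 0.5 * on_axis.sum(axis=1)
        seeing_right = ((frontal | lateral) & right).sum(axis=1) \
            + 0.5 * on_axis.sum(axis=1)
        res["left_all"][lo:hi] = seeing_left / counts
        res["right_all"][lo:hi] = seeing_right / counts
    return res


def classify_frame(fractions: dict[str, float],
                   params: ClassifierParams = ClassifierParams()) -> str:
    """'blind' when the blind fraction reaches the threshold, else 'oriented'."""
    return "blind" if fractions["blind"] >= params.blind_threshold else "oriented"


def classify_track(track: pd.DataFrame, valid_mask: np.ndarray,
                   layout: ChamberLayout,
                   angles: FieldAngles = FieldAngles(),
                   params: ClassifierParams = ClassifierParams()) -> pd.DataFrame:
    """Per-frame visual-field fractions and oriented/blind class.

    ``valid_mask`` marks frames that passed quality control; excluded frames
    carry NaN fractions and class ``excluded``.  Frames with a degenerate
    head pose are classed ``invalid``.
    """
    pose = estimate_head_pose(track)
    usable = np.asarray(valid_mask, bool) & pose["valid"].to_numpy()
    n_invalid = int((np.asarray(valid_mask, bool) & ~pose["valid"].to_numpy()).sum())
    if n_invalid:
        log.info("%d QC-passed frames had a degenerate head pose", n_invalid)

    out = pd.DataFrame({
        "frame_index": track["frame_index"].to_numpy(),
        "time": track["time"].to_numpy(),
        "bearing_deg": pose["bearing_deg"].to_numpy(),
    })
    for k in FRACTION_COLUMNS:
        out[k] = np.nan
    out["frame_class"] = "excluded"
    out.loc[np.asarray(valid_mask, bool) & ~pose["valid"].to_numpy(),
            "frame_class"] = "invalid"

    if usable.any():
        origins = pose.loc[usable, ["origin_x", "origin_y"]].to_numpy()
        bearings = pose.loc[usable, "bearing_deg"].to_numpy()
        fr = stimulus_field_fractions_track(origins, bearings,
                                            layout.stimulus_segment, angles, params)
        idx = np.flatnonzero(usable)
        for k in FRACTION_COLUMNS:
            out.loc[idx, k] = fr[k]
        out.loc[idx, "frame_class"] = np.where(
            fr["blind"] >= params.blind_threshold, "blind", "oriented")
    return out
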