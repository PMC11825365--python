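"""Keypoint quality control: inter-keypoint distance z-scores and likelihoods.

Misidentified body parts show up as frames whose inter-keypoint distances
(head-left ear, head-right ear, left ear-right ear) are far from the
session's typical head geometry, and as frames the pose estimator itself is
unsure about.  Two filters reproduce that exclusion:

1. For each of the three distance series, the mean and standard deviation
   are computed over ALL frames of the track (population SD, N
   denominator); a frame is excluded when any distance has |z| strictly
   greater than the threshold (default 3), z = (Y - mean) / SD.
2. A frame is excluded when any body part's likelihood is strictly below
   the cutoff (default 0.9).

Both filters are evaluated on the full track, so their order is immaterial;
the valid mask is the complement of the union of the two exclusions.
Frames with non-finite coordinates are marked invalid (excluded) rather
than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chamber import BODYPARTS

log = logging.getLogger(__name__)

DISTANCE_PAIRS = (("head_top", "left_ear"), ("head_top", "right_ear"),
                  ("left_ear", "right_ear"))
DISTANCE_NAMES = tuple(f"{a}-{b}" for a, b in DISTANCE_PAIRS)


@dataclass(frozen=True)
class QCParams:
    z_threshold: float = 3.0
    likelihood_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not self.z_threshold > 0:
            raise ValueError("z_threshold must be > 0")
        if not 0.0 < self.likelihood_threshold <= 1.0:
            raise ValueError("likelihood_threshold must be in (0, 1]")


@dataclass
class QCReport:
    n_frames: int
    n_excluded_zscore: int
    n_excluded_likelihood: int
    n_excluded_total: int
    distance_means: dict[str, float]
    distance_stds: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"quantity": "n_frames", "value": self.n_frames},
                {"quantity": "n_excluded_zscore", "value": self.n_excluded_zscore},
                {"quantity": "n_excluded_likelihood",
                 "value": self.n_excluded_likelihood},
                {"quantity": "n_excluded_total", "value": self.n_excluded_total}]
        for name in DISTANCE_NAMES:
            rows.append({"quantity": f"mean[{name}]",
                         "value": self.distance_means[name]})
            rows.append({"quantity": f"std[{name}]",
                         "value": self.distance_stds[name]})
        return pd.DataFrame(rows)


def pairwise_distances(track: pd.DataFrame) -> np.ndarray:
    """(n, 3) Euclidean distances head-L ear, head-R ear, L ear-R ear.

    NaN where any involved coordinate is non-finite (the frame is treated
    as invalid downstream, no exception is raised).
    """
    coords = {bp: track[[f"{bp}_x", f"{bp}_y"]].to_numpy(float) for bp in BODYPARTS}
    out = np.empty((len(track), 3))
    for j, (a, b) in enumerate(DISTANCE_PAIRS):
        d = coords[a] - coords[b]
        with np.errstate(invalid="ignore"):
            out[:, j] = np.hypot(d[:, 0], d[:, 1])
    out[~np.isfinite(out)] = np.nan
    return out


def zscore_filter(track: pd.DataFrame, params: QCParams = QCParams(),
                  ) -> tuple[np.ndarray, dict[str, float], dict[str, float]]:
    """Exclusion mask (True = excluded) from distance z-scores, plus stats.

    A zero-variance distance series excludes nothing (its z is defined 0).
    Frames with non-finite distances are excluded and ignored in the stats.
    """
    if len(track) < 2:
        raise ValueError("z-score filter needs at least 2 frames")
    dist = pairwise_distances(track)
    finite = np.isfinite(dist).all(axis=1)
    means, stds = {}, {}
    excluded = ~finite
    for j, name in enumerate(DISTANCE_NAMES):
        y = dist[finite, j]
        mu = float(np.mean(y)) if y.size else np.nan
        sd = float(np.std(y)) if y.size else np.nan  # population SD (N)
        means[name], stds[name] = mu, sd
        if not np.isfinite(sd) or sd == 0.0:
            log.info("distance %s has zero variance; series excludes nothing", name)
            continue
        with np.errstate(invalid="ignore"):
            z = (dist[:, j] - mu) / sd
        excluded |= np.abs(z) > params.z_threshold  # strict: |z| == thr retained
    return excluded, means, stds


def likelihood_filter(track: pd.DataFrame,
                      params: QCParams = QCParams()) -> np.ndarray:
    """Exclusion mask: any body part's likelihood strictly below the cutoff."""
    lik = track[[f"{bp}_likelihood" for bp in BODYPARTS]].to_numpy(float)
    return (lik < params.likelihood_threshold).any(axis=1)


def apply_qc(track: pd.DataFrame,
             params: QCParams = QCParams()) -> tuple[np.ndarray, QCReport]:
    """Valid-frame mask (True = keep) and the exclusion report.

    A frame failing both filters counts once in ``n_excluded_total``.
    An empty track yields an empty mask and a zero-count report.
    """
    if len(track) == 0:
        return (np.zeros(0, bool),
                QCReport(0, 0, 0, 0,
                         {n: np.nan for n in DISTANCE_NAMES},
                         {n: np.nan for n in DISTANCE_NAMES}))
    z_excl, means, stds = zscore_filter(track, params)
    lik_excl = likelihood_filter(track, params)
    union = z_excl | lik_excl
    report = QCReport(
        n_frames=len(track),
        n_excluded_zscore=int(z_excl.sum()),
        n_excluded_likelihood=int(lik_excl.sum()),
        n_excluded_total=int(union.sum()),
        distance_means=means, distance_stds=stds)
    return ~union, report
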