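import numpy as np
import pandas as pd
import pytest

from rcptvfa import (AgentParams, ChamberLayout, PoseNoise, simulate_session,
                     stage3_schedule, synthesize_pose, tot_probe_schedule)


def make_track(nose, left_ear, right_ear, likelihoods=None) -> pd.DataFrame:
    """Build a keypoint track DataFrame from per-frame coordinate arrays."""
    nose = np.atleast_2d(np.asarray(nose, float))
    left_ear = np.atleast_2d(np.asarray(left_ear, float))
    right_ear = np.atleast_2d(np.asarray(right_ear, float))
    n = len(nose)
    if likelihoods is None:
        likelihoods = np.ones((n, 3))
    likelihoods = np.atleast_2d(np.asarray(likelihoods, float))
    return pd.DataFrame({
        "frame_index": np.arange(n), "time": np.arange(n) / 30.0,
        "head_top_x": nose[:, 0], "head_top_y": nose[:, 1],
        "head_top_likelihood": likelihoods[:, 0],
        "left_ear_x": left_ear[:, 0], "left_ear_y": left_ear[:, 1],
        "left_ear_likelihood": likelihoods[:, 1],
        "right_ear_x": right_ear[:, 0], "right_ear_y": right_ear[:, 1],
        "right_ear_likelihood": likelihoods[:, 2],
    })


@pytest.fixture(scope="session")
def stage3_session():
    """A deterministic 45-min Stage-3 session (events + truth)."""
    schedule = stage3_schedule()
    events, truth = simulate_session(schedule, AgentParams(), seed=11)
    return schedule, events, truth


@pytest.fixture(scope="session")
def clean_tot_session():
    """A noise-free TOT-probe session with pose, for exact round trips.

    10-min session at 30 fps keeps unit tests fast; the full-length
    90-min round trip lives in the acceptance suite.
    """
    schedule = tot_probe_schedule(session_duration=600.0)
    agent = AgentParams(orientation_p0=0.85)
    events, truth = simulate_session(schedule, agent, seed=21)
    layout = ChamberLayout()
    track = synthesize_pose(events, truth, layout,
                            PoseNoise(jitter_px=0.0, outlier_rate=0.0,
                                      low_likelihood_rate=0.0), seed=22)
    return schedule, events, truth, layout, track
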