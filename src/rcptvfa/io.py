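"""Readers and writers for the pipeline's on-disk formats.

Two external dialects are supported: an ABET-style event CSV with header
``timestamp_s,event,trial_id,is_correction`` and the DeepLabCut output
dialect for keypoint tracks — three header rows (scorer / bodyparts /
coords), the first column being the frame index and every body part
contributing ``x, y, likelihood`` columns.  Body-part columns are resolved
by header name, never by position.  Ground truth travels as plain sidecar
CSVs.  All files are UTF-8; writes are deterministic so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chamber import BODYPARTS, COORDS
from .simulate import EVENT_TYPES

EVENT_HEADER = ["timestamp_s", "event", "trial_id", "is_correction"]


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


def write_event_csv(events: pd.DataFrame, path) -> None:
    """Write an event log; timestamps keep microsecond precision."""
    df = events.copy()
    df["timestamp_s"] = df["timestamp_s"].map(lambda v: f"{v:.6f}")
    df["is_correction"] = df["is_correction"].astype(int)
    df["trial_id"] = df["trial_id"].astype("Int64")
    df[EVENT_HEADER].to_csv(path, index=False)


def read_event_csv(path, time_offset: float = 0.0) -> pd.DataFrame:
    """Read an event log written by :func:`write_event_csv`.

    ``time_offset`` is subtracted from every timestamp, accommodating logs
    whose clock is not session-relative.
    """
    df = pd.read_csv(path, dtype={"event": str}, float_precision="round_trip")
    missing = [c for c in EVENT_HEADER if c not in df.columns]
    if missing:
        raise ParseError(f"event CSV {path} missing columns {missing}")
    bad = ~df["event"].isin(EVENT_TYPES)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"event CSV {path}: unknown event {df['event'].iloc[i]!r} at row {i + 2}")
    ts = pd.to_numeric(df["timestamp_s"], errors="coerce")
    if ts.isna().any():
        i = int(ts.isna().idxmax())
        raise ParseError(
            f"event CSV {path}: non-numeric timestamp at row {i + 2}, "
            f"column 'timestamp_s'")
    out = pd.DataFrame({
        "timestamp_s": ts.astype(float) - time_offset,
        "event": df["event"],
        "trial_id": pd.to_numeric(df["trial_id"], errors="coerce").astype("Int64"),
        "is_correction": df["is_correction"].astype(int).astype(bool),
    })
    return out


def write_dlc_csv(track: pd.DataFrame, path, scorer: str = "synthetic") -> None:
    """Write a keypoint track in the DeepLabCut three-header-row dialect."""
    cols = pd.MultiIndex.from_tuples(
        [(scorer, bp, c) for bp in BODYPARTS for c in COORDS],
        names=["scorer", "bodyparts", "coords"])
    data = {(scorer, bp, c): track[f"{bp}_{c}"].to_numpy()
            for bp in BODYPARTS for c in COORDS}
    df = pd.DataFrame(data, index=track["frame_index"].to_numpy())
    df.columns = cols
    df.to_csv(path)


def read_dlc_csv(path) -> pd.DataFrame:
    """Read a DeepLabCut-dialect keypoint CSV into the flat track layout.

    Columns are matched by the ``bodyparts``/``coords`` header rows, so any
    column ordering is accepted.  Returns columns ``frame_index, time`` —
    with ``time`` left as NaN (the frame rate lives in the chamber layout)
    — plus ``{bodypart}_{x,y,likelihood}``.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                         float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as e:
        raise ParseError(f"{path}: not a DLC three-header CSV ({e})") from e
    if df.columns.nlevels != 3:
        raise ParseError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    by_name: dict[tuple[str, str], pd.Series] = {}
    for col in df.columns:
        _, bp, coord = (str(level).strip() for level in col)
        by_name[(bp, coord)] = df[col]
    out = pd.DataFrame({"frame_index": df.index.to_numpy()})
    out["time"] = np.nan
    for bp in BODYPARTS:
        for c in COORDS:
            if (bp, c) not in by_name:
                raise ParseError(
                    f"{path}: missing column for body part {bp!r}, coord {c!r}")
            vals = pd.to_numeric(by_name[(bp, c)], errors="coerce")
            if vals.isna().any():
                row = int(vals.isna().to_numpy().argmax())
                raise ParseError(
                    f"{path}: non-numeric cell at data row {row + 1}, "
                    f"column ({bp}, {c})")
            out[f"{bp}_{c}"] = vals.to_numpy(float)
    fi = pd.to_numeric(out["frame_index"], errors="coerce")
    if fi.isna().any():
        raise ParseError(f"{path}: non-numeric frame index")
    out["frame_index"] = fi.astype(np.int64)
    return out


def attach_frame_times(track: pd.DataFrame, frame_rate: float) -> pd.DataFrame:
    track = track.copy()
    track["time"] = track["frame_index"] / float(frame_rate)
    return track


def write_truth_sidecars(truth, outdir) -> dict[str, Path]:
    """Write ground-truth trial and frame tables next to the session files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["trials"] = outdir / "truth_trials.csv"
    truth.trials.to_csv(paths["trials"], index=False)
    if truth.frames is not None:
        paths["frames"] = outdir / "truth_frames.csv"
        truth.frames.to_csv(paths["frames"], index=False)
    paths["bins"] = outdir / "truth_bins.csv"
    truth.bins.to_csv(paths["bins"], index=False)
    return paths
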