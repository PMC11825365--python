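"""End-to-end orchestration: simulate -> pose -> QC -> visual field ->
trial orientation -> metrics, driven by a declarative YAML config.

One global seed is fanned out (via ``numpy.random.SeedSequence``) into
independent per-stage streams, so the event log and the pose track can be
regenerated separately yet reproducibly.  Every stage writes its
intermediate table as CSV and the run ends with a manifest recording
versions, seeds, row counts, exclusion counts and SHA-256 checksums; with
a fixed seed two runs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .chamber import ChamberLayout
from .metrics import RateCorrection, bin_summaries, session_report
from .pose_qc import QCParams, apply_qc
from .pose_synth import PoseNoise, synthesize_pose
from .simulate import (AgentParams, ConfigurationError, SCHEDULE_PRESETS,
                       SessionSchedule, simulate_session)
from .trials import BinSpec, build_trials, orient_trials, orientation_index
from .visual_field import ClassifierParams, FieldAngles, classify_track

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A pipeline config field is unknown or out of domain."""


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
    try:
        return cls(**{k: (tuple(map(tuple, v)) if isinstance(v, list)
                          and v and isinstance(v[0], list) else
                          tuple(v) if isinstance(v, list) else v)
                      for k, v in section.items()})
    except (ValueError, ConfigurationError) as e:
        raise ConfigError(f"{name}: {e}") from e


@dataclass
class PipelineConfig:
    """Fully declarative description of one pipeline run."""

    schedule: SessionSchedule = field(
        default_factory=SCHEDULE_PRESETS["tot_probe"])
    agent: AgentParams = field(default_factory=AgentParams)
    layout: ChamberLayout = field(default_factory=ChamberLayout)
    noise: PoseNoise = field(default_factory=PoseNoise)
    qc: QCParams = field(default_factory=QCParams)
    angles: FieldAngles = field(default_factory=FieldAngles)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    bin_width: float = 900.0
    rate_correction: str = "half_count"
    include_correction_trials: bool = False
    count_iti_restarts: bool = True
    seed: int = 0
    subject: str = "sim"
    session: str = "s1"

    _TOP_KEYS = ("schedule", "agent", "layout", "noise", "qc", "angles",
                 "classifier", "bin_width", "rate_correction",
                 "include_correction_trials", "count_iti_restarts", "seed",
                 "subject", "session")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls._TOP_KEYS)
        if unknown:
            raise ConfigError(f"unknown top-level config keys {sorted(unknown)}")
        kw: dict = {}
        if "schedule" in d:
            sched = dict(d["schedule"])
            preset = sched.pop("preset", None)
            if preset is not None:
                if preset not in SCHEDULE_PRESETS:
                    raise ConfigError(
                        f"schedule.preset: unknown preset {preset!r}; "
                        f"choose from {sorted(SCHEDULE_PRESETS)}")
                try:
                    kw["schedule"] = SCHEDULE_PRESETS[preset](**sched)
                except (TypeError, ConfigurationError) as e:
                    raise ConfigError(f"schedule: {e}") from e
            else:
                kw["schedule"] = _build(SessionSchedule, sched, "schedule")
        for key, typ in (("agent", AgentParams), ("layout", ChamberLayout),
                         ("noise", PoseNoise), ("qc", QCParams),
                         ("angles", FieldAngles),
                         ("classifier", ClassifierParams)):
            if key in d:
                kw[key] = _build(typ, dict(d[key]), key)
        for key in ("bin_width", "rate_correction", "include_correction_trials",
                    "count_iti_restarts", "seed", "subject", "session"):
            if key in d:
                kw[key] = d[key]
        cfg = cls(**kw)
        RateCorrection(cfg.rate_correction)  # validate
        if cfg.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(2)
        return {"simulate": int(state[0] & 0x7FFFFFFF),
                "pose": int(state[1] & 0x7FFFFFFF)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _analysis_stages(cfg: PipelineConfig, events: pd.DataFrame,
                     track: pd.DataFrame, outdir: Path,
                     manifest: dict) -> dict:
    correction = RateCorrection(cfg.rate_correction)
    bins = BinSpec(bin_width=cfg.bin_width,
                   session_duration=cfg.schedule.session_duration)

    valid_mask, qc_report = apply_qc(track, cfg.qc)
    pd.DataFrame({"frame_index": track["frame_index"],
                  "valid": valid_mask.astype(int)}).to_csv(
        outdir / "qc_mask.csv", index=False)
    qc_report.to_frame().to_csv(outdir / "qc_report.csv", index=False)
    log.info("QC: %d/%d frames excluded", qc_report.n_excluded_total,
             qc_report.n_frames)

    frame_classes = classify_track(track, valid_mask, cfg.layout,
                                   cfg.angles, cfg.classifier)
    frame_classes.to_csv(outdir / "frame_classes.csv", index=False,
                         float_format="%.6f")

    trials = build_trials(events, cfg.schedule)
    trial_orient = orient_trials(trials, frame_classes)
    trials.to_csv(outdir / "trials.csv", index=False, float_format="%.6f")
    trial_orient.to_csv(outdir / "trial_orientation.csv", index=False)
    n_indet = int(trial_orient["oriented"].isna().sum())
    log.info("trials: %d (%d correction, %d indeterminate orientation)",
             len(trials), int(trials["is_correction"].sum()), n_indet)

    oi = orientation_index(trial_orient, trials, bins, by_response_type=True,
                           include_correction=cfg.include_correction_trials)
    oi.to_csv(outdir / "orientation_bins.csv", index=False,
              float_format="%.6f")

    summary = bin_summaries(trials, events, bins, trial_orient,
                            correction=correction,
                            count_iti_restarts=cfg.count_iti_restarts)
    summary.to_csv(outdir / "bin_summary.csv", index=False,
                   float_format="%.6f")
    report = session_report(summary, cfg.subject, cfg.session)
    report.to_csv(outdir / "session_report.csv", index=False,
                  float_format="%.6f")

    manifest["counts"].update({
        "frames": int(len(track)),
        "frames_excluded_qc": int(qc_report.n_excluded_total),
        "frames_excluded_zscore": int(qc_report.n_excluded_zscore),
        "frames_excluded_likelihood": int(qc_report.n_excluded_likelihood),
        "trials": int(len(trials)),
        "correction_trials": int(trials["is_correction"].sum()),
        "indeterminate_trials": n_indet,
        "bins": int(bins.n_bins),
    })
    return {"trials": trials, "trial_orientation": trial_orient,
            "frame_classes": frame_classes, "orientation_bins": oi,
            "bin_summary": summary, "session_report": report,
            "qc_report": qc_report, "valid_mask": valid_mask}


def _finalize_manifest(manifest: dict, outdir: Path) -> None:
    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))}
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _base_manifest(cfg: PipelineConfig) -> dict:
    import rcptvfa
    return {
        "versions": {"rcptvfa": rcptvfa.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "seed": cfg.seed, "stage_seeds": cfg.stage_seeds(),
        "counts": {},
    }


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Simulate a session, synthesise its pose track, and analyse both.

    Writes every intermediate file plus ``manifest.json`` under ``outdir``
    and returns the in-memory tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    manifest = _base_manifest(cfg)

    events, truth = simulate_session(cfg.schedule, cfg.agent, seeds["simulate"])
    track = synthesize_pose(events, truth, cfg.layout, cfg.noise, seeds["pose"],
                            lateral_bound=cfg.angles.lateral,
                            blind_threshold=cfg.classifier.blind_threshold)
    rio.write_event_csv(events, outdir / "events.csv")
    rio.write_dlc_csv(track, outdir / "pose_dlc.csv")
    rio.write_truth_sidecars(truth, outdir)
    manifest["counts"]["events"] = int(len(events))
    manifest["end_reason"] = truth.end_reason

    # Analyse the persisted representation (not the in-memory one) so that
    # run_all and a later `analyze` of the same files agree byte for byte.
    events = rio.read_event_csv(outdir / "events.csv")
    track = rio.attach_frame_times(rio.read_dlc_csv(outdir / "pose_dlc.csv"),
                                   cfg.layout.frame_rate)
    result = _analysis_stages(cfg, events, track, outdir, manifest)
    result["events"], result["truth"], result["track"] = events, truth, track
    _finalize_manifest(manifest, outdir)
    result["manifest"] = manifest
    return result


def analyze(events_file, pose_file, cfg: PipelineConfig, outdir,
            time_offset: float = 0.0) -> dict:
    """Run the analysis stages only, on user-supplied ABET/DLC exports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events = rio.read_event_csv(events_file, time_offset=time_offset)
    track = rio.attach_frame_times(rio.read_dlc_csv(pose_file),
                                   cfg.layout.frame_rate)
    manifest = _base_manifest(cfg)
    manifest["counts"]["events"] = int(len(events))
    manifest["inputs"] = {"events": str(events_file), "pose": str(pose_file)}
    result = _analysis_stages(cfg, events, track, outdir, manifest)
    result["events"], result["track"] = events, track
    _finalize_manifest(manifest, outdir)
    result["manifest"] = manifest
    return result
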