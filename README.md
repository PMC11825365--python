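# rcptvfa

Pose-derived vigilance analysis for the rodent Continuous Performance
Test (rCPT).

In the rCPT — a touchscreen go/no-go attention task — performance
declines within a session (the vigilance decrement, or time-on-task
effect). The decline is ambiguous on its own: the animal may stop
*looking* at the screen, or keep looking while its perceptual/decisional
processing changes. `rcptvfa` disambiguates the two by joining the
operant event log with a head-keypoint track from markerless pose
estimation: it computes where the animal's visual field lies on every
video frame, flags each trial as *oriented* (≥ 1 frame of its limited-hold
window with the stimulus outside the blind field) and sets the resulting
**orientation index** against signal-detection performance in 15-min time
bins. A stable orientation index alongside a falling response rate is the
signature of a true vigilance decrement rather than physical
disengagement.

The pipeline stages are:

1. **synthetic data** — a discrete-event simulator of rCPT sessions
   (ABET-style event CSV + ground truth) and a matching
   DeepLabCut-dialect keypoint synthesiser, so every stage is testable
   without recordings;
2. **pose QC** — frames excluded when any inter-keypoint distance has
   |z| > 3 (z = (Y − mean)/SD over all frames) or any body-part
   likelihood < 0.9;
3. **visual field** — head pose from the ear midpoint and nose keypoint;
   sectors frontal (|θ| ≤ 20°), lateral (≤ 103.4°) and blind; per-frame
   fractions of the stimulus segment in each sector; a frame is *blind*
   when ≥ 90 % of the stimulus lies in the blind field;
4. **trial orientation** — trials parsed from the event log, limited-hold
   windows `[onset, outcome)`, the ≥ 1-oriented-frame rule, and the
   orientation index = oriented / total trials per bin;
5. **metrics** — HR = hits/(hits+misses), FAR = FA/(FA+CR),
   d′ = z(HR) − z(FAR), c = −(z(HR)+z(FAR))/2, impulsivity % =
   100·(centre ITI touches)/(ITIs initiated), response rate =
   (hits+FA)/all trials, latency means/SDs, tidy long-format export;
6. **CLI** — `rcptvfa` with subcommands `simulate`, `qc`, `vfa`,
   `orient`, `metrics`, `run-all`, `analyze`.

## Worked example

Simulate and analyse a 10-minute Stage-3 session at 30 fps:

```sh
cat > demo.yaml <<'EOF'
schedule: {preset: stage3, session_duration: 600}
layout: {frame_rate: 30}
seed: 5
EOF
rcptvfa run-all --config demo.yaml --out demo_out
```

which prints

```
 bin_index  hit_rate  false_alarm_rate  d_prime  response_rate  orientation_index
         0  0.722222          0.090909 1.924634        0.42029           0.927536
```

One 600-s bin: the agent hit 72 % of targets and false-alarmed on 9 % of
non-targets, giving a sensitivity d′ = z(0.722) − z(0.091) ≈ 1.92 (good
discrimination); it touched on 42 % of all trials, and 93 % of trials had
at least one limited-hold frame with the stimulus inside the seeing
field — close to the simulated agent's orientation policy of 0.92.
`demo_out/` contains every intermediate table (`events.csv`,
`pose_dlc.csv`, `qc_report.csv`, `frame_classes.csv`, `trials.csv`,
`orientation_bins.csv`, `bin_summary.csv`, `session_report.csv`, ground
truth sidecars) plus `manifest.json` with seeds, counts and checksums;
rerunning the same config and seed reproduces all files byte for byte.
Real ABET/DeepLabCut exports go through the same stages with
`rcptvfa analyze events.csv pose.csv --config demo.yaml --out out/`.

The library mirrors the CLI one-to-one:

```python
from rcptvfa import PipelineConfig, run_all
result = run_all(PipelineConfig.from_yaml("demo.yaml"), "demo_out")
result["bin_summary"]          # counts, HR/FAR, d', c, latencies, index
```

## Documentation

`docs/methods.md` describes the task and agent model, the geometry and
its conventions, the QC and classification rules, every tunable default,
and the package's numerical choices and limitations.
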