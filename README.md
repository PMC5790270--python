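# mibdyn

Simulation and analysis toolkit for the temporal dynamics of **motion-induced
blindness (MIB)** under perceptual grouping.

In an MIB display, salient static targets superimposed on a moving mask
pattern repeatedly vanish from awareness and reappear, even though they are
physically present the whole time. Observers report these perceptual states
by holding a key per target while it is invisible. Two grouping
manipulations are of interest:

- **Common region** — the targets sit inside a *single* shared mask rather
  than each in its own mask. The hypothesis is that this makes their
  disappearances and reappearances more *synchronized* without necessarily
  changing how much total invisibility occurs.
- **Connectedness** — a *line* drawn between the targets. The hypothesis is
  that this *reduces* total invisibility (connected objects resist
  disappearing) without necessarily synchronizing the two targets.

`mibdyn` provides:

1. a **synthetic data generator** that produces key-press event logs from a
   coupled alternating-renewal model of perceptual states, with a motor
   model (response latency and noise) layered on top and full ground truth
   retained;
2. an **analysis pipeline** that validates and repairs event logs, converts
   them into invisibility intervals, calibrates per-observer simultaneity
   windows from scripted control trials, classifies events as simultaneous
   or not, and computes the summary measures below;
3. a **command-line interface** (`mibdyn`) that runs the whole round trip
   and writes CSV/JSON outputs.

## Measures

For each trial of duration `T_TRIAL`:

- **P_DISAPPEAR** `= T_DISAPPEAR / T_TRIAL`, where `T_DISAPPEAR` is the
  duration of the *union* of all per-target invisibility intervals — the
  fraction of the trial during which at least one target was invisible.
- **P_SIM** `= (D_SIM + R_SIM) / (D_TOTAL + R_TOTAL)` — the fraction of
  disappearance (`D`) and reappearance (`R`) events classified as
  simultaneous across targets. An event is simultaneous when it belongs to
  a cluster of events on distinct keys whose span falls inside the
  observer's calibrated finger-press-asynchrony window `[min, max]`
  (strict mode) or simply below `max` (relaxed mode).
- **P_KANIZSA** `= T_KANIZSA / (T_TRIAL − T_DISAPPEAR)` — for displays
  where an illusory (Kanizsa-style) figure can be seen only while all
  targets are visible: the fraction of full-visibility time during which
  the figure was reported.

The asynchrony windows are calibrated per observer, per event type and per
cluster size from *control* sessions in which physical target offsets and
onsets are scripted, so the window captures pure motor asynchrony.

## Worked example

Run a complete synthetic study — 15 observers, the 2×2 grid of
(single mask vs two masks) × (line vs no line) — and summarize it:

```python
from mibdyn import RunConfig, run_pipeline

cfg = RunConfig(out_dir="out/demo", seed=7, n_observers=15)
result = run_pipeline(cfg)
print(result["summary"].to_string(index=False))
```

Output (abridged to the two headline measures):

```
    measure           condition  n     mean      sem
p_disappear    single_mask_line 15 0.266589 0.008656
p_disappear single_mask_no_line 15 0.452138 0.009983
p_disappear      two_masks_line 15 0.309856 0.008805
p_disappear   two_masks_no_line 15 0.444301 0.009190
      p_sim    single_mask_line 15 0.388345 0.020835
      p_sim single_mask_no_line 15 0.387989 0.015760
      p_sim      two_masks_line 15 0.164924 0.022026
      p_sim   two_masks_no_line 15 0.138948 0.012602
```

Reading off the main effects: the connecting line lowers `p_disappear` from
about 0.448 to 0.288 (≈ −0.16) while leaving `p_sim` nearly unchanged
(+0.01); the single common mask raises `p_sim` from about 0.152 to 0.388
(≈ +0.24) while leaving `p_disappear` nearly unchanged (−0.02). These match
the effects injected by the generator (see `docs/methods.md`). Means and
SEMs are within-subject adjusted (each observer recentred to the grand mean
before averaging).

The same run from the command line:

```bash
mibdyn demo --out-dir out/demo --seed 7
```

which writes `main_logs.csv`, `control_logs.csv`, `control_schedule.csv`,
`ground_truth.csv`, `calibration.csv`, `trial_measures.csv`,
`condition_summary.csv`, `manifest.json` and `report.txt`. The stage
commands `mibdyn validate`, `mibdyn calibrate` and `mibdyn analyze` run the
pipeline piecewise on existing CSV logs; `mibdyn run config.yaml` drives a
fully configured run.

## Repository layout

- `src/mibdyn/event_log.py` — key-press log schema, I/O, validation/repair
- `src/mibdyn/intervals.py` — invisibility intervals and sweep-line union
- `src/mibdyn/synthetic.py` — coupled renewal generator and motor model
- `src/mibdyn/fpa.py` — control-trial matching and window calibration
- `src/mibdyn/simultaneity.py` — event extraction and optimal clustering
- `src/mibdyn/measures.py` — trial measures, exclusions, summaries
- `src/mibdyn/pipeline.py`, `src/mibdyn/cli.py` — orchestration and CLI
- `docs/methods.md` — model, parameters and numerical choices
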