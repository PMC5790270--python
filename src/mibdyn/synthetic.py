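"""Synthetic observers for motion-induced blindness report streams.

Every downstream stage of the pipeline is validated by parameter recovery
against this generator, which emulates three processes:

* **Perceptual dynamics** — each target alternates between visible and
  invisible states.  Episode durations are gamma-distributed (the
  conventional description of dominance durations in multistable
  perception), and a *coupling* probability lets a spontaneous transition
  recruit the other targets, producing genuinely simultaneous group events
  with a known per-event label.
* **Motor responses** — each perceptual transition is reported with a
  truncated-normal key latency, independent across keys, turning the
  ground-truth trajectory into a press/release event log.
* **Scripted control sessions** — physical disappearances of random target
  subsets with invisible episodes uniform on [1.5, 3] s and visible
  episodes uniform on [2, 4] s, used to calibrate each observer's
  finger-press-asynchrony window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .event_log import ANY_TARGET, KANIZSA, PRESS, RELEASE, EventLog, EventRecord

VISIBLE = "visible"
INVISIBLE = "invisible"

#: Default target key labels.
def target_keys(n_targets: int) -> list[str]:
    return [f"T{i + 1}" for i in range(n_targets)]


@dataclass(frozen=True)
class ObserverProfile:
    """Motor-latency parameters of one simulated observer.

    Latencies are truncated normal (non-negative), independent across keys
    and events; separate press/release parameters because reporting an
    onset and an offset need not be equally fast.
    """

    observer_id: str
    latency_mean_press: float = 0.35
    latency_sd_press: float = 0.05
    latency_mean_release: float = 0.35
    latency_sd_release: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("latency_mean_press", "latency_sd_press",
                     "latency_mean_release", "latency_sd_release"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimCondition:
    """Perceptual-dynamics parameters of one display condition."""

    name: str = "condition"
    n_targets: int = 2
    mean_invisible_duration: float = 2.0
    mean_visible_duration: float = 4.0
    duration_shape: float = 3.0
    coupling: float = 0.0
    recruit_lag_sd: float = 0.03
    trial_duration: float = 120.0

    def __post_init__(self) -> None:
        for name in ("mean_invisible_duration", "mean_visible_duration",
                     "duration_shape", "trial_duration"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if not (math.isfinite(self.recruit_lag_sd) and self.recruit_lag_sd >= 0):
            raise ValueError("recruit_lag_sd must be finite and >= 0")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")


@dataclass(frozen=True)
class Transition:
    """One ground-truth perceptual state change of one target."""

    time: float
    new_state: str  # VISIBLE or INVISIBLE
    recruited: bool
    group_id: int   # transitions sharing a group_id changed state together


@dataclass
class GroundTruthTrajectory:
    """Per-target ground-truth state-change sequences for one trial.

    All targets start visible at t = 0.  Per target, states strictly
    alternate and times strictly increase within [0, trial_duration).
    """

    trial_duration: float
    transitions: dict[str, list[Transition]] = field(default_factory=dict)

    @property
    def keys(self) -> list[str]:
        return sorted(self.transitions)

    def invisible_intervals(self, key: str) -> list[tuple[float, float]]:
        """Closed-form invisible episodes; an episode ongoing at trial end
        is truncated at ``trial_duration``."""
        out = []
        onset = None
        for tr in self.transitions[key]:
            if tr.new_state == INVISIBLE:
                onset = tr.time
            elif onset is not None:
                out.append((onset, tr.time))
                onset = None
        if onset is not None:
            out.append((onset, self.trial_duration))
        return out

    def union_invisible_fraction(self) -> float:
        """True fraction of the trial with at least one target invisible."""
        from .intervals import IntervalTrack, union_duration

        tracks = [
            IntervalTrack(key=k, intervals=self.invisible_intervals(k))
            for k in self.keys
        ]
        return union_duration(tracks) / self.trial_duration

    def simultaneity_fraction(self) -> float:
        """True fraction of transitions belonging to multi-target groups.

        This is the ground truth against which the pipeline's P_SIM is
        judged: an event is simultaneous iff its state change was shared
        (recruiter or recruited) with at least one other target.
        """
        sizes: dict[int, int] = {}
        total = 0
        for trs in self.transitions.values():
            for tr in trs:
                sizes[tr.group_id] = sizes.get(tr.group_id, 0) + 1
                total += 1
        if total == 0:
            return float("nan")
        sim = sum(n for n in sizes.values() if n >= 2)
        return sim / total

    def to_frame(self, observer_id: str = "", trial_id: str = "",
                 condition: str = "") -> pd.DataFrame:
        rows = [
            (observer_id, trial_id, condition, key, tr.time, tr.new_state,
             tr.recruited, tr.group_id)
            for key in self.keys
            for tr in self.transitions[key]
        ]
        return pd.DataFrame(
            rows,
            columns=["observer_id", "trial_id", "condition", "target",
                     "time", "new_state", "recruited_flag", "group_id"],
        )


def simulate_target_states(
    cond: SimCondition, seed: int | np.random.Generator
) -> GroundTruthTrajectory:
    """Simulate coupled alternating-renewal perceptual trajectories.

    Per target, invisible and visible episode durations are drawn from
    gamma distributions with the condition's means and common shape.  With
    probability ``coupling``, a spontaneous transition is copied to every
    other target whose current state permits the same change, at a lag of
    ``|Normal(0, recruit_lag_sd)|``; recruited targets redraw their next
    spontaneous transition from the recruited change.  The trajectory is
    truncated at ``trial_duration``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    keys = target_keys(cond.n_targets)
    shape = cond.duration_shape

    def draw_duration(state: str) -> float:
        mean = (
            cond.mean_invisible_duration
            if state == INVISIBLE
            else cond.mean_visible_duration
        )
        return float(rng.gamma(shape, mean / shape))

    state = {k: VISIBLE for k in keys}
    next_flip = {k: draw_duration(VISIBLE) for k in keys}
    last_time = {k: -1.0 for k in keys}
    transitions: dict[str, list[Transition]] = {k: [] for k in keys}
    group_id = 0
    T = cond.trial_duration

    while True:
        j = min(keys, key=lambda k: next_flip[k])
        t = next_flip[j]
        if t >= T:
            break
        old_state = state[j]
        new_state = INVISIBLE if old_state == VISIBLE else VISIBLE
        group_id += 1
        transitions[j].append(Transition(t, new_state, False, group_id))
        state[j] = new_state
        last_time[j] = t
        next_flip[j] = t + draw_duration(new_state)

        if cond.coupling > 0 and rng.random() < cond.coupling:
            for k in keys:
                if k == j or state[k] != old_state:
                    continue
                lag = abs(rng.normal(0.0, cond.recruit_lag_sd)) if cond.recruit_lag_sd else 0.0
                tk = t + lag
                if tk >= T or tk <= last_time[k]:
                    continue
                transitions[k].append(Transition(tk, new_state, True, group_id))
                state[k] = new_state
                last_time[k] = tk
                next_flip[k] = tk + draw_duration(new_state)

    return GroundTruthTrajectory(trial_duration=T, transitions=transitions)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One draw from Normal(mean, sd) truncated to [0, inf)."""
    if sd == 0.0:
        return mean
    while True:  # acceptance rate >= Phi(mean/sd); fine for mean >= 0
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)


def apply_motor_model(
    traj: GroundTruthTrajectory,
    obs: ObserverProfile,
    *,
    trial_id: str = "trial1",
    condition: str = "condition",
    rng: np.random.Generator | None = None,
) -> EventLog:
    """Turn a ground-truth trajectory into a keypress log.

    Each invisible onset becomes a press at ``onset + latency`` and each
    offset a release likewise (truncated-normal latencies, independent
    across keys and events).  A pair whose latencies invert its internal
    order, or a pair whose press would precede the previous pair's
    release on the same key, is dropped so per-key alternation is
    preserved.  Responses to an episode ongoing at trial end produce a
    press with no release; responses past trial end are clipped to it.
    """
    if rng is None:
        rng = np.random.default_rng(obs.seed)
    T = traj.trial_duration
    records: list[EventRecord] = []
    for key in traj.keys:
        episodes = _raw_invisible_episodes(traj, key)
        prev_release = -math.inf
        for onset, offset in episodes:
            press = onset + _truncated_normal(
                rng, obs.latency_mean_press, obs.latency_sd_press
            )
            if offset is None:  # episode ongoing at trial end: press only
                release = None
            else:
                release = offset + _truncated_normal(
                    rng, obs.latency_mean_release, obs.latency_sd_release
                )
                if release > T:
                    release = T
                if press >= release:  # latency inverted the pair; drop it
                    continue
            if press >= T or press <= prev_release:
                continue
            records.append(
                EventRecord(obs.observer_id, trial_id, condition, key, PRESS, press)
            )
            if release is not None:
                records.append(
                    EventRecord(
                        obs.observer_id, trial_id, condition, key, RELEASE, release
                    )
                )
                prev_release = release
            else:
                prev_release = T
    return EventLog(
        observer_id=obs.observer_id,
        trial_id=trial_id,
        condition=condition,
        trial_duration=T,
        records=records,
    )


def _raw_invisible_episodes(
    traj: GroundTruthTrajectory, key: str
) -> list[tuple[float, float | None]]:
    """Invisible episodes with ``None`` marking 'ongoing at trial end'."""
    out: list[tuple[float, float | None]] = []
    onset = None
    for tr in traj.transitions[key]:
        if tr.new_state == INVISIBLE:
            onset = tr.time
        elif onset is not None:
            out.append((onset, tr.time))
            onset = None
    if onset is not None:
        out.append((onset, None))
    return out


# ---------------------------------------------------------------------------
# Scripted control sessions (FPA calibration data)
# ---------------------------------------------------------------------------

SCHEDULE_COLUMNS = [
    "observer_id", "trial_id", "episode", "onset", "offset",
    "targets", "cluster_size",
]


def generate_control_session(
    n_targets: int,
    obs: ObserverProfile,
    n_trials: int,
    seed: int | np.random.Generator,
    *,
    trial_duration: float = 120.0,
    invisible_range: tuple[float, float] = (1.5, 3.0),
    visible_range: tuple[float, float] = (2.0, 4.0),
) -> tuple[pd.DataFrame, list[EventLog]]:
    """Simulate the scripted physical-disappearance control experiment.

    Each cycle draws a full-visibility episode uniform on ``visible_range``
    followed by a disappearance episode uniform on ``invisible_range`` of a
    uniformly random nonempty subset of targets, all disappearing exactly
    simultaneously.  Responses come from :func:`apply_motor_model`; the
    returned schedule keeps the ground-truth subsets for matching.
    """
    if n_targets not in (2, 3):
        raise ValueError("control sessions support 2 or 3 targets")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    keys = target_keys(n_targets)
    subsets = [
        [k for k, bit in zip(keys, format(m, f"0{n_targets}b")) if bit == "1"]
        for m in range(1, 2 ** n_targets)
    ]

    rows = []
    logs = []
    for trial in range(n_trials):
        trial_id = f"control{trial + 1}"
        transitions: dict[str, list[Transition]] = {k: [] for k in keys}
        t = 0.0
        episode = 0
        group_id = 0
        while True:
            t += rng.uniform(*visible_range)
            dur = rng.uniform(*invisible_range)
            onset, offset = t, min(t + dur, trial_duration)
            if onset >= trial_duration:
                break
            subset = subsets[rng.integers(len(subsets))]
            episode += 1
            group_id += 1
            for k in subset:
                transitions[k].append(Transition(onset, INVISIBLE, False, group_id))
                if offset < trial_duration:
                    transitions[k].append(Transition(offset, VISIBLE, False, group_id))
            rows.append(
                (obs.observer_id, trial_id, episode, onset, offset,
                 "+".join(subset), len(subset))
            )
            t += dur
        traj = GroundTruthTrajectory(trial_duration=trial_duration,
                                     transitions=transitions)
        logs.append(
            apply_motor_model(traj, obs, trial_id=trial_id,
                              condition="control", rng=rng)
        )
    schedule = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    return schedule, logs


# ---------------------------------------------------------------------------
# Whole-experiment generation
# ---------------------------------------------------------------------------

@dataclass
class ExperimentData:
    """Everything one simulated study produces."""

    main_logs: list[EventLog]
    ground_truth: pd.DataFrame          # one row per observer x condition x trial
    trajectories: dict[tuple[str, str, str], GroundTruthTrajectory]
    control_schedules: dict[str, pd.DataFrame]
    control_logs: dict[str, list[EventLog]]
    observers: list[ObserverProfile]


def generate_experiment(
    design: dict[str, SimCondition],
    observers: list[ObserverProfile],
    seed: int,
    *,
    style: str = "per_target",
    kanizsa_visible_fraction: float = 0.6,
    kanizsa_mean_cycle: float = 6.0,
    n_control_trials: int = 2,
    n_repeats: int = 1,
) -> ExperimentData:
    """Simulate a full study: main trials plus per-observer control sessions.

    ``style="per_target"`` gives one designated key per target (the
    two-by-two grouping designs).  ``style="any_key_kanizsa"`` emits
    instead an ANY_TARGET stream (union of the targets' invisibility) and
    a KANIZSA stream held while the illusory triangle is perceived, with
    the triangle visible for ``kanizsa_visible_fraction`` of
    full-visibility time.
    """
    if not design:
        raise ValueError("empty design grid")
    if style not in ("per_target", "any_key_kanizsa"):
        raise ValueError(f"unknown style {style!r}")
    root = np.random.default_rng(seed)

    main_logs: list[EventLog] = []
    gt_rows = []
    trajectories = {}
    control_schedules = {}
    control_logs = {}

    n_targets = max(c.n_targets for c in design.values())
    for obs in observers:
        obs_rng = np.random.default_rng(root.integers(2 ** 31))
        schedule, clogs = generate_control_session(
            min(n_targets, 3), obs, n_control_trials, obs_rng
        )
        control_schedules[obs.observer_id] = schedule
        control_logs[obs.observer_id] = clogs

        for cond_name, cond in design.items():
            for rep in range(n_repeats):
                trial_id = f"{cond_name}_r{rep + 1}"
                traj = simulate_target_states(cond, obs_rng)
                if style == "per_target":
                    log = apply_motor_model(
                        traj, obs, trial_id=trial_id, condition=cond_name,
                        rng=obs_rng,
                    )
                    true_pk = math.nan
                else:
                    log, true_pk = _kanizsa_log(
                        traj, obs, trial_id, cond_name, obs_rng,
                        kanizsa_visible_fraction, kanizsa_mean_cycle,
                        cond.duration_shape,
                    )
                main_logs.append(log)
                trajectories[(obs.observer_id, cond_name, trial_id)] = traj
                gt_rows.append(
                    (obs.observer_id, cond_name, trial_id,
                     traj.union_invisible_fraction(),
                     traj.simultaneity_fraction(), true_pk)
                )

    ground_truth = pd.DataFrame(
        gt_rows,
        columns=["observer_id", "condition", "trial_id",
                 "true_p_disappear", "true_p_sim", "true_p_kanizsa"],
    )
    return ExperimentData(
        main_logs=main_logs,
        ground_truth=ground_truth,
        trajectories=trajectories,
        control_schedules=control_schedules,
        control_logs=control_logs,
        observers=list(observers),
    )


def _kanizsa_log(
    traj: GroundTruthTrajectory,
    obs: ObserverProfile,
    trial_id: str,
    condition: str,
    rng: np.random.Generator,
    visible_fraction: float,
    mean_cycle: float,
    shape: float,
):
    """Build an ANY_TARGET + KANIZSA log from a multi-target trajectory.

    The illusory-triangle percept is an independent alternating-renewal
    process with stationary visible fraction ``visible_fraction``; the
    triangle is only reportable while every inducer is visible, so the
    KANIZSA stream is that process intersected with full-visibility time.
    """
    from .intervals import IntervalTrack, union_intervals

    T = traj.trial_duration
    tracks = [
        IntervalTrack(key=k, intervals=traj.invisible_intervals(k))
        for k in traj.keys
    ]
    any_invisible = union_intervals(tracks)

    # Alternating renewal for the triangle percept on [0, T].
    mean_on = visible_fraction * mean_cycle
    mean_off = (1.0 - visible_fraction) * mean_cycle
    kan_on: list[tuple[float, float]] = []
    t, on = 0.0, True  # start in the visible state
    while t < T:
        dur = rng.gamma(shape, (mean_on if on else mean_off) / shape)
        if on:
            kan_on.append((t, min(t + dur, T)))
        t += dur
        on = not on

    full_vis = _complement(any_invisible, T)
    kan_reported = _intersect(kan_on, full_vis)
    tvis = sum(e - s for s, e in full_vis)
    true_pk = (
        sum(e - s for s, e in kan_reported) / tvis if tvis > 0 else math.nan
    )

    # Wrap both streams as a two-"target" trajectory for the motor model.
    transitions: dict[str, list[Transition]] = {ANY_TARGET: [], KANIZSA: []}
    gid = 0
    for s, e in any_invisible:
        gid += 1
        transitions[ANY_TARGET].append(Transition(s, INVISIBLE, False, gid))
        if e < T:
            transitions[ANY_TARGET].append(Transition(e, VISIBLE, False, gid))
    # KANIZSA key semantics: held while the triangle is PERCEIVED, so each
    # perceived episode maps onto a press/release pair.
    for s, e in kan_reported:
        gid += 1
        if s == e:
            continue
        transitions[KANIZSA].append(Transition(s, INVISIBLE, False, gid))
        if e < T:
            transitions[KANIZSA].append(Transition(e, VISIBLE, False, gid))
    wrapped = GroundTruthTrajectory(trial_duration=T, transitions=transitions)
    log = apply_motor_model(wrapped, obs, trial_id=trial_id,
                            condition=condition, rng=rng)
    return log, true_pk


def _complement(intervals: list[tuple[float, float]], T: float):
    out = []
    prev = 0.0
    for s, e in intervals:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < T:
        out.append((prev, T))
    return out


def _intersect(a: list[tuple[float, float]], b: list[tuple[float, float]]):
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out
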