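"""Trial-level grouping measures and study-level summaries.

Three proportions quantify the perceptual dynamics:

* ``P_DISAPPEAR = T_DISAPPEAR / T_TRIAL`` — the fraction of the trial
  during which at least one target was reported invisible (strength of
  the suppression).
* ``P_SIM = (D_SIM + R_SIM) / (D_TOTAL + R_TOTAL)`` — the fraction of
  disappearance plus reappearance events classified simultaneous across
  targets (tendency of the targets to vanish or return as a group).
* ``P_KANIZSA = T_KANIZSA / (T_TRIAL - T_DISAPPEAR)`` — the fraction of
  full-visibility time during which the illusory triangle was reported.

Undefined ratios (zero denominators) are missing values, never zeros, so
they cannot silently bias condition means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_log import ANY_TARGET, KANIZSA, SPECIAL_KEYS, EventLog, validate_and_repair
from .fpa import FpaWindowSet
from .intervals import IntervalTrack, intervals_from_events, total_duration, union_duration
from .simultaneity import EventCounts, cluster_events, count_events, extract_events


@dataclass
class TrialMeasures:
    """All measures and raw quantities of one analyzed trial."""

    observer_id: str
    trial_id: str
    condition: str
    t_trial: float
    t_disappear: float
    d_total: int = 0
    d_sim: int = 0
    r_total: int = 0
    r_sim: int = 0
    t_kanizsa: float = math.nan

    @property
    def p_disappear(self) -> float:
        return self.t_disappear / self.t_trial

    @property
    def p_sim(self) -> float:
        denom = self.d_total + self.r_total
        return (self.d_sim + self.r_sim) / denom if denom else math.nan

    @property
    def p_sim_disappearance(self) -> float:
        return self.d_sim / self.d_total if self.d_total else math.nan

    @property
    def p_sim_reappearance(self) -> float:
        return self.r_sim / self.r_total if self.r_total else math.nan

    @property
    def p_kanizsa(self) -> float:
        if math.isnan(self.t_kanizsa):
            return math.nan
        return p_kanizsa_from_times(self.t_kanizsa, self.t_disappear, self.t_trial)

    def as_dict(self) -> dict:
        return {
            "observer_id": self.observer_id,
            "trial_id": self.trial_id,
            "condition": self.condition,
            "t_trial": self.t_trial,
            "t_disappear": self.t_disappear,
            "t_kanizsa": self.t_kanizsa,
            "d_total": self.d_total,
            "d_sim": self.d_sim,
            "r_total": self.r_total,
            "r_sim": self.r_sim,
            "p_disappear": self.p_disappear,
            "p_sim": self.p_sim,
            "p_sim_disappearance": self.p_sim_disappearance,
            "p_sim_reappearance": self.p_sim_reappearance,
            "p_kanizsa": self.p_kanizsa,
        }


def p_disappear(
    tracks: list[IntervalTrack],
    trial_duration: float,
    restrict_to: set[str] | None = None,
) -> float:
    """Proportion of trial time with at least one target invisible."""
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    return union_duration(tracks, restrict_to) / trial_duration


def p_sim(counts: EventCounts) -> float:
    """Proportion of events classified simultaneous; NaN when no events."""
    denom = counts.d_total + counts.r_total
    return (counts.d_sim + counts.r_sim) / denom if denom else math.nan


def p_kanizsa_from_times(
    t_kanizsa: float, t_disappear: float, t_trial: float
) -> float:
    """Triangle-visibility proportion of full-visibility time.

    The ratio can exceed 1 when the observer held the triangle key while
    also reporting a target invisible; such values are clamped to 1 with
    a warning.  A non-positive denominator (targets invisible the whole
    trial) yields a missing value.
    """
    denom = t_trial - t_disappear
    if denom <= 0:
        return math.nan
    value = t_kanizsa / denom
    if value > 1:
        warnings.warn(
            f"P_KANIZSA = {value:.3f} > 1 (triangle reported during partial "
            "invisibility); clamped to 1",
            stacklevel=2,
        )
        return 1.0
    return value


def p_kanizsa(
    kanizsa_track: IntervalTrack,
    any_target_track: IntervalTrack,
    trial_duration: float,
) -> float:
    return p_kanizsa_from_times(
        total_duration(kanizsa_track),
        total_duration(any_target_track),
        trial_duration,
    )


def analyze_trial(
    log: EventLog,
    windows: FpaWindowSet | None = None,
    *,
    mode: str = "strict",
    debounce_s: float = 0.0,
) -> TrialMeasures:
    """Run one main-trial log through the full measure pipeline.

    Per-target logs yield P_DISAPPEAR and the simultaneity counts (an FPA
    window set is then required).  Logs using the pooled response mapping
    (ANY_TARGET / KANIZSA keys) yield P_DISAPPEAR from the ANY_TARGET
    stream and P_KANIZSA; simultaneity is not analyzable there.
    """
    repaired, _ = validate_and_repair(log, debounce_s=debounce_s)
    tracks = intervals_from_events(repaired)
    by_key = {t.key: t for t in tracks}

    if ANY_TARGET in by_key or KANIZSA in by_key:
        any_track = by_key.get(ANY_TARGET, IntervalTrack(ANY_TARGET, []))
        kan_track = by_key.get(KANIZSA, IntervalTrack(KANIZSA, []))
        return TrialMeasures(
            observer_id=log.observer_id,
            trial_id=log.trial_id,
            condition=log.condition,
            t_trial=log.trial_duration,
            t_disappear=total_duration(any_track),
            t_kanizsa=total_duration(kan_track),
        )

    target_tracks = [t for t in tracks if t.key not in SPECIAL_KEYS]
    if windows is None:
        raise ValueError("per-target logs require a calibrated FPA window set")
    events = extract_events(target_tracks, log.trial_duration)
    clusters = cluster_events(events, windows, mode=mode)
    counts = count_events(clusters)
    return TrialMeasures(
        observer_id=log.observer_id,
        trial_id=log.trial_id,
        condition=log.condition,
        t_trial=log.trial_duration,
        t_disappear=union_duration(target_tracks),
        d_total=counts.d_total,
        d_sim=counts.d_sim,
        r_total=counts.r_total,
        r_sim=counts.r_sim,
    )


def measures_frame(measures: list[TrialMeasures]) -> pd.DataFrame:
    """Long-form trial-level table."""
    return pd.DataFrame([m.as_dict() for m in measures])


def exclusion_filter(
    trial_table: pd.DataFrame, threshold: int = 5
) -> pd.Series:
    """Observer-level inclusion flags from per-condition disappearance counts.

    An observer is excluded when the total number of individual
    disappearance events in any condition falls below ``threshold``
    (strictly fewer; exactly ``threshold`` events keeps the observer).
    """
    per_cond = (
        trial_table.groupby(["observer_id", "condition"])["d_total"].sum()
    )
    min_per_obs = per_cond.groupby("observer_id").min()
    included = min_per_obs >= threshold
    for obs in included.index[~included]:
        warnings.warn(
            f"observer {obs!r} excluded: fewer than {threshold} disappearance "
            "events in at least one condition",
            stacklevel=2,
        )
    included.name = "included"
    return included


def apply_exclusions(
    trial_table: pd.DataFrame, threshold: int = 5
) -> pd.DataFrame:
    included = exclusion_filter(trial_table, threshold)
    keep = trial_table["observer_id"].map(included)
    return trial_table[keep.fillna(False)].reset_index(drop=True)


def within_subject_adjust(
    table: pd.DataFrame,
    value_col: str,
    *,
    observer_col: str = "observer_id",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Cousineau-style adjustment for repeated-measures error bars.

    Each value is recentred as ``value - observer_mean + grand_mean``,
    removing between-observer offsets so that error bars reflect the
    within-observer variability.  Observers missing any condition are left
    unadjusted (NaN in the adjusted column) with a warning.  Condition
    means are preserved when the design is complete.
    """
    df = table.copy()
    conditions = set(df[condition_col].unique())
    complete = (
        df.groupby(observer_col)[condition_col]
        .agg(lambda s: set(s) == conditions)
    )
    incomplete = complete.index[~complete]
    for obs in incomplete:
        warnings.warn(
            f"observer {obs!r} misses conditions; adjustment skipped",
            stacklevel=2,
        )
    mask = df[observer_col].isin(complete.index[complete])
    sub = df[mask]
    obs_means = sub.groupby(observer_col)[value_col].transform("mean")
    grand_mean = sub[value_col].mean()
    adjusted = pd.Series(np.nan, index=df.index, dtype=float)
    adjusted[mask] = sub[value_col] - obs_means + grand_mean
    df[f"{value_col}_adj"] = adjusted
    return df


def summarize(
    trial_table: pd.DataFrame,
    value_col: str,
    *,
    observer_col: str = "observer_id",
    condition_col: str = "condition",
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-condition n, mean, and (adjusted) SEM.

    The mean is of the raw values; the SEM is computed on the
    within-subject adjusted values when ``adjust`` is set (the adjustment
    preserves condition means, so the mean is unaffected).  A condition
    with a single observer reports a missing SEM.
    """
    df = trial_table.dropna(subset=[value_col])
    if adjust:
        df = within_subject_adjust(
            df, value_col, observer_col=observer_col, condition_col=condition_col
        )
        sem_col = f"{value_col}_adj"
    else:
        sem_col = value_col

    rows = []
    for cond, grp in df.groupby(condition_col, sort=True):
        n = grp[observer_col].nunique()
        mean = grp[value_col].mean()
        sem = grp[sem_col].sem() if n > 1 else math.nan
        rows.append((cond, n, mean, sem))
    return pd.DataFrame(rows, columns=[condition_col, "n", "mean", "sem"])


def pooled_condition_p_sim(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Alternative aggregation: pool event counts across a condition's
    trials per observer before dividing (vs. the default per-trial ratio)."""
    grp = trial_table.groupby(["observer_id", "condition"], sort=True)[
        ["d_sim", "r_sim", "d_total", "r_total"]
    ].sum()
    denom = grp["d_total"] + grp["r_total"]
    out = grp.assign(
        p_sim=np.where(denom > 0, (grp["d_sim"] + grp["r_sim"]) / denom, np.nan)
    )
    return out.reset_index()
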