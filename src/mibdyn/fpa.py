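"""Finger-press-asynchrony (FPA) calibration.

Even when several targets physically disappear at the same instant, an
observer's key responses are spread over tens of milliseconds.  A control
session with scripted simultaneous physical disappearances measures that
spread per observer: the *asynchrony* of a response group is its span
(latest minus earliest response time), and the calibrated window is the
[min, max] of the observed asynchronies.  In main trials, a group of
perceptual events is later labelled simultaneous when its span falls
inside this window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .event_log import PRESS, RELEASE, EventLog

#: Perceptual event types.  A press reports a disappearance onset, a
#: release a reappearance; the main analysis keeps the two separate.
DISAPPEARANCE = "disappearance"
REAPPEARANCE = "reappearance"

_EVENT_OF_ACTION = {PRESS: DISAPPEARANCE, RELEASE: REAPPEARANCE}


class CalibrationError(ValueError):
    """Raised when no usable control responses exist for an observer."""


@dataclass(frozen=True)
class MatchedGroup:
    """Responses of one observer to one scripted multi-target episode."""

    observer_id: str
    event_type: str      # disappearance (presses) or reappearance (releases)
    cluster_size: int
    times: tuple[float, ...]

    @property
    def span(self) -> float:
        return max(self.times) - min(self.times)


@dataclass(frozen=True)
class FpaWindow:
    """[min, max] asynchrony bounds for one (event type, cluster size)."""

    observer_id: str
    event_type: str
    cluster_size: int
    min_asynchrony: float
    max_asynchrony: float
    n_samples: int
    fallback: bool = False  # True when pooled across cluster sizes

    def __post_init__(self) -> None:
        if not 0 <= self.min_asynchrony <= self.max_asynchrony:
            raise ValueError("window bounds must satisfy 0 <= min <= max")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def contains(self, span: float, *, relaxed: bool = False) -> bool:
        lo = 0.0 if relaxed else self.min_asynchrony
        return lo <= span <= self.max_asynchrony


def match_responses_to_schedule(
    schedule: pd.DataFrame,
    log: EventLog,
    *,
    match_tolerance: float = 1.5,
) -> tuple[list[MatchedGroup], int]:
    """Match control-log responses to scripted multi-target episodes.

    For every scripted episode involving at least two targets, collect the
    first press after each target's scripted onset and the first release
    after each scripted offset, within ``match_tolerance`` seconds.  An
    episode whose presses (resp. releases) are not all found contributes no
    press (resp. release) group; each such miss increments the skip count.
    """
    if not log.records:
        raise CalibrationError(
            f"empty control log for observer {log.observer_id!r}"
        )
    presses: dict[str, list[float]] = {}
    releases: dict[str, list[float]] = {}
    for rec in log.records:
        (presses if rec.action == PRESS else releases).setdefault(
            rec.key, []
        ).append(rec.time)

    episodes = schedule[
        (schedule["trial_id"] == log.trial_id)
        & (schedule["cluster_size"] >= 2)
    ]
    groups: list[MatchedGroup] = []
    skipped = 0
    for row in episodes.itertuples():
        targets = row.targets.split("+")
        for anchor, pool, ev_type in (
            (row.onset, presses, DISAPPEARANCE),
            (row.offset, releases, REAPPEARANCE),
        ):
            times = []
            for key in targets:
                t = _first_after(pool.get(key, []), anchor, match_tolerance)
                if t is None:
                    break
                times.append(t)
            if len(times) == len(targets):
                groups.append(
                    MatchedGroup(
                        observer_id=log.observer_id,
                        event_type=ev_type,
                        cluster_size=len(targets),
                        times=tuple(times),
                    )
                )
            else:
                skipped += 1
    return groups, skipped


def _first_after(times: list[float], anchor: float, tol: float) -> float | None:
    for t in times:  # log order is sorted, so first hit is earliest
        if anchor <= t <= anchor + tol:
            return t
    return None


@dataclass
class FpaWindowSet:
    """All calibrated windows of one observer, with pooled fallback.

    ``window_for`` returns the window for an exact (event type, cluster
    size); when that size was never observed it falls back to the window
    pooled across sizes for the event type, flagged via ``fallback``.
    """

    observer_id: str
    windows: dict[tuple[str, int], FpaWindow] = field(default_factory=dict)
    pooled: dict[str, FpaWindow] = field(default_factory=dict)

    def window_for(self, event_type: str, cluster_size: int) -> FpaWindow:
        key = (event_type, cluster_size)
        if key in self.windows:
            return self.windows[key]
        if event_type in self.pooled:
            return self.pooled[event_type]
        raise CalibrationError(
            f"observer {self.observer_id!r}: no FPA window for "
            f"{event_type}/{cluster_size} and no pooled fallback"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (w.observer_id, w.event_type, w.cluster_size, w.min_asynchrony,
             w.max_asynchrony, w.n_samples, w.fallback)
            for w in self.windows.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["observer_id", "event_type", "cluster_size",
                     "min_asynchrony", "max_asynchrony", "n_samples",
                     "fallback_flag"],
        )


def calibrate_fpa(
    groups: list[MatchedGroup], *, pool_event_types: bool = False
) -> FpaWindowSet:
    """Turn matched control groups into per-observer FPA windows.

    The window for each (event type, cluster size) is the [min, max] of
    the groups' spans.  With ``pool_event_types`` the press and release
    asynchronies are pooled into a single window per cluster size, applied
    to both event types.  Pooled-across-size windows are always computed
    as the fallback for sizes without samples.
    """
    if not groups:
        raise CalibrationError("no matched control groups: calibration failed")
    observer_ids = {g.observer_id for g in groups}
    if len(observer_ids) != 1:
        raise CalibrationError("calibrate_fpa expects groups of one observer")
    observer_id = observer_ids.pop()

    def key_of(g: MatchedGroup):
        ev = "pooled" if pool_event_types else g.event_type
        return ev, g.cluster_size

    by_key: dict[tuple[str, int], list[float]] = {}
    by_event: dict[str, list[float]] = {}
    for g in groups:
        by_key.setdefault(key_of(g), []).append(g.span)
        ev = "pooled" if pool_event_types else g.event_type
        by_event.setdefault(ev, []).append(g.span)

    out = FpaWindowSet(observer_id=observer_id)
    for (ev, size), spans in by_key.items():
        targets = (DISAPPEARANCE, REAPPEARANCE) if ev == "pooled" else (ev,)
        for t in targets:
            out.windows[(t, size)] = FpaWindow(
                observer_id, t, size, min(spans), max(spans), len(spans)
            )
    for ev, spans in by_event.items():
        targets = (DISAPPEARANCE, REAPPEARANCE) if ev == "pooled" else (ev,)
        for t in targets:
            out.pooled[t] = FpaWindow(
                observer_id, t, 0, min(spans), max(spans), len(spans),
                fallback=True,
            )
    return out


def windows_from_frame(df: pd.DataFrame) -> dict[str, FpaWindowSet]:
    """Rebuild per-observer window sets from a calibration table CSV."""
    out: dict[str, FpaWindowSet] = {}
    for row in df.itertuples():
        ws = out.setdefault(row.observer_id, FpaWindowSet(row.observer_id))
        w = FpaWindow(
            row.observer_id, row.event_type, int(row.cluster_size),
            float(row.min_asynchrony), float(row.max_asynchrony),
            int(row.n_samples), bool(row.fallback_flag),
        )
        ws.windows[(w.event_type, w.cluster_size)] = w
        ws.pooled.setdefault(w.event_type, w)
    return out
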