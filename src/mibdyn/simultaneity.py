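"""Classify disappearance/reappearance events as simultaneous across targets.

Consecutive same-type events on distinct keys are grouped into clusters
bounded by the observer's calibrated finger-press asynchrony window; a
multi-event cluster whose span (latest minus earliest time) falls between
the window's minimum and maximum is labelled simultaneous.  A *relaxed*
mode drops the lower bound, treating any span up to the maximum as
simultaneous.

Clustering is an exact dynamic program over order-respecting partitions of
each event-type stream, maximizing the number of events in simultaneous
clusters.  A one-pass greedy scan would usually give the same answer, but
it can pair events whose span falls below the calibrated minimum, or pair
early events at the cost of a better later cluster, missing genuinely
simultaneous groups; the dynamic program is immune to both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .fpa import DISAPPEARANCE, REAPPEARANCE, FpaWindowSet
from .intervals import IntervalTrack

MODES = ("strict", "relaxed")


@dataclass(frozen=True)
class PerceptualEvent:
    """A disappearance (interval start) or reappearance (interval end)."""

    key: str
    event_type: str
    time: float


@dataclass(frozen=True)
class EventCluster:
    """A maximal greedy group of same-type events on distinct keys."""

    cluster_id: int
    event_type: str
    events: tuple[PerceptualEvent, ...]
    simultaneous: bool

    @property
    def span(self) -> float:
        times = [e.time for e in self.events]
        return max(times) - min(times)

    @property
    def size(self) -> int:
        return len(self.events)


class EventCounts(NamedTuple):
    """Per-trial event tallies entering the simultaneity proportion."""

    d_total: int
    d_sim: int
    r_total: int
    r_sim: int


def extract_events(
    tracks: list[IntervalTrack], trial_duration: float
) -> list[PerceptualEvent]:
    """Emit one disappearance per interval start, one reappearance per end.

    An interval that runs to ``trial_duration`` was closed artificially
    (the episode was still ongoing when the trial stopped) and emits no
    reappearance.
    """
    events = []
    for track in tracks:
        for start, end in track.intervals:
            events.append(PerceptualEvent(track.key, DISAPPEARANCE, start))
            if end < trial_duration:
                events.append(PerceptualEvent(track.key, REAPPEARANCE, end))
    events.sort(key=lambda e: (e.time, e.key))
    return events


def cluster_events(
    events: list[PerceptualEvent],
    windows: FpaWindowSet,
    *,
    mode: str = "strict",
) -> list[EventCluster]:
    """Span-bounded clustering of same-type events.

    Each event-type stream (time-sorted) is partitioned into runs of
    consecutive events; a multi-event run is admissible when its keys are
    distinct and its span is at most the maximum asynchrony for its size.
    Among all admissible partitions, a dynamic program selects one that
    maximizes the number of events in simultaneous clusters (``strict``:
    span between the window's min and max; ``relaxed``: at most max); ties
    are broken in favour of longer, earlier-starting clusters.  Singletons
    are never simultaneous.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    clusters: list[EventCluster] = []
    cluster_id = 0
    for ev_type in (DISAPPEARANCE, REAPPEARANCE):
        stream = [e for e in events if e.event_type == ev_type]
        for members, sim in _partition_stream(stream, windows, ev_type, mode):
            cluster_id += 1
            clusters.append(
                EventCluster(cluster_id, ev_type, tuple(members), sim)
            )
    return clusters


def _segment_status(
    seg: list[PerceptualEvent],
    windows: FpaWindowSet,
    ev_type: str,
    mode: str,
) -> tuple[bool, bool]:
    """(admissible, simultaneous) for one candidate cluster."""
    if len(seg) == 1:
        return True, False
    if len({e.key for e in seg}) != len(seg):
        return False, False
    w = windows.window_for(ev_type, len(seg))
    span = seg[-1].time - seg[0].time
    if span > w.max_asynchrony:
        return False, False
    return True, w.contains(span, relaxed=(mode == "relaxed"))


def _partition_stream(
    stream: list[PerceptualEvent],
    windows: FpaWindowSet,
    ev_type: str,
    mode: str,
) -> list[tuple[list[PerceptualEvent], bool]]:
    """Optimal order-respecting partition of one event-type stream.

    ``best[i]`` is the maximal number of simultaneous events among
    admissible partitions of the first ``i`` events; clusters can span at
    most as many events as there are distinct keys.
    """
    n = len(stream)
    if n == 0:
        return []
    max_size = len({e.key for e in stream})
    best = [0] * (n + 1)
    choice = [0] * (n + 1)  # start index of the cluster ending at i
    for i in range(1, n + 1):
        best_score, best_j = -1, i - 1
        # prefer longer (earlier-starting) clusters on ties
        for j in range(max(0, i - max_size), i):
            seg = stream[j:i]
            ok, sim = _segment_status(seg, windows, ev_type, mode)
            if not ok:
                continue
            score = best[j] + (len(seg) if sim else 0)
            if score > best_score:
                best_score, best_j = score, j
        best[i] = best_score
        choice[i] = best_j
    # reconstruct
    bounds = []
    i = n
    while i > 0:
        j = choice[i]
        bounds.append((j, i))
        i = j
    bounds.reverse()
    out = []
    for j, i in bounds:
        seg = stream[j:i]
        _, sim = _segment_status(seg, windows, ev_type, mode)
        out.append((seg, sim))
    return out


def count_events(clusters: list[EventCluster]) -> EventCounts:
    """Tally per-target events; simultaneous counts are events belonging
    to simultaneous clusters, so the proportion reaches 1 exactly when
    every event is shared."""
    d_total = d_sim = r_total = r_sim = 0
    for c in clusters:
        if c.event_type == DISAPPEARANCE:
            d_total += c.size
            if c.simultaneous:
                d_sim += c.size
        else:
            r_total += c.size
            if c.simultaneous:
                r_sim += c.size
    return EventCounts(d_total, d_sim, r_total, r_sim)


def clusters_to_rows(clusters: list[EventCluster]) -> list[tuple]:
    """Flatten clusters for the per-trial event table
    (key, event_type, time, cluster_id, simultaneous_flag)."""
    return [
        (e.key, c.event_type, e.time, c.cluster_id, c.simultaneous)
        for c in clusters
        for e in c.events
    ]
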