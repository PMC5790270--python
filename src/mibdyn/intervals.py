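"""Half-open invisibility intervals on the trial timeline.

Each press–release pair on a target key becomes one ``[start, end)``
interval of reported invisibility.  The half-open convention makes abutting
intervals measure-additive: no boundary instant is ever double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .event_log import PRESS, RELEASE, EventLog


@dataclass
class IntervalTrack:
    """Disjoint, sorted invisibility intervals for one key."""

    key: str
    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"invalid interval [{start}, {end})")
        self.intervals = sorted(self.intervals)
        for (_, e0), (s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError("intervals overlap within one track")


def intervals_from_events(log: EventLog) -> list[IntervalTrack]:
    """Pair presses with releases into per-key interval tracks.

    The log must already satisfy per-key press/release alternation
    (run :func:`mibdyn.event_log.validate_and_repair` first); any
    violation raises ``ValueError``.  Keys with no events are absent from
    the result.
    """
    by_key: dict[str, list] = {}
    for rec in log.records:
        by_key.setdefault(rec.key, []).append(rec)

    tracks = []
    for key in sorted(by_key):
        recs = by_key[key]
        intervals: list[tuple[float, float]] = []
        open_press = None
        for rec in recs:
            if rec.action == PRESS:
                if open_press is not None:
                    raise ValueError(
                        f"key {key!r}: press at {rec.time} while already "
                        "pressed; validate the log first"
                    )
                open_press = rec.time
            elif rec.action == RELEASE:
                if open_press is None:
                    raise ValueError(
                        f"key {key!r}: release at {rec.time} with no open "
                        "press; validate the log first"
                    )
                if rec.time > open_press:
                    intervals.append((open_press, rec.time))
                open_press = None
        if open_press is not None:
            raise ValueError(
                f"key {key!r}: unterminated press at {open_press}; "
                "validate the log first"
            )
        tracks.append(IntervalTrack(key=key, intervals=intervals))
    return tracks


def union_duration(
    tracks: list[IntervalTrack], restrict_to: set[str] | None = None
) -> float:
    """Total time covered by at least one interval across the tracks.

    Sweep-line over the sorted endpoints; exact on the continuous
    timeline (no sampling grid).  ``restrict_to`` limits the union to a
    subset of keys.
    """
    intervals: list[tuple[float, float]] = []
    for track in tracks:
        if restrict_to is not None and track.key not in restrict_to:
            continue
        intervals.extend(track.intervals)
    if not intervals:
        return 0.0
    intervals.sort()
    total = 0.0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
    total += cur_end - cur_start
    return total


def total_duration(track: IntervalTrack) -> float:
    """Sum of interval lengths of one track."""
    return float(sum(end - start for start, end in track.intervals))


def union_intervals(tracks: list[IntervalTrack]) -> list[tuple[float, float]]:
    """Merged intervals covered by at least one track ("any target invisible")."""
    intervals = sorted(iv for t in tracks for iv in t.intervals)
    if not intervals:
        return []
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def write_intervals(tracks: list[IntervalTrack], path) -> None:
    """Export tracks as 3-column tab-separated text (key, start, end).

    Times are seconds on the trial clock; the layout is BED-like for easy
    inspection but is not a genomic BED file.
    """
    with open(path, "w") as fh:
        fh.write("# key\tstart_s\tend_s\n")
        for track in tracks:
            for start, end in track.intervals:
                fh.write(f"{track.key}\t{start:.6f}\t{end:.6f}\n")
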