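"""Keypress event logs: the raw continuous-report format.

Observers report target invisibility by holding down a designated key per
target (or, in the Kanizsa-style experiment, one key for "at least one
target invisible" and one for "illusory triangle perceived").  A log is an
ordered stream of press/release records on a trial-relative clock in
seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

PRESS = "press"
RELEASE = "release"
ACTIONS = (PRESS, RELEASE)

#: Special key labels for experiments with pooled-report response mappings.
ANY_TARGET = "ANY_TARGET"
KANIZSA = "KANIZSA"
SPECIAL_KEYS = frozenset({ANY_TARGET, KANIZSA})

CSV_COLUMNS = ["observer_id", "trial_id", "condition", "key", "action", "time"]


class SchemaError(ValueError):
    """Raised when an event-log file violates the CSV schema."""


@dataclass(frozen=True)
class EventRecord:
    """One press or release of one key at a trial-relative time (s)."""

    observer_id: str
    trial_id: str
    condition: str
    key: str
    action: str
    time: float

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise SchemaError(f"unknown action {self.action!r}")
        if not self.time >= 0:
            raise SchemaError(f"negative time {self.time!r}")


def _sort_key(rec: EventRecord):
    # Stable order: time, then key label, then release before press at ties.
    return (rec.time, rec.key, 0 if rec.action == RELEASE else 1)


@dataclass
class EventLog:
    """All records of one trial, sorted by time.

    ``trial_duration`` is the scripted trial length in seconds (the clock
    origin is trial onset).  ``n_targets`` counts the distinct ordinary
    target keys seen in the log; special keys are excluded.
    """

    observer_id: str
    trial_id: str
    condition: str
    trial_duration: float
    records: list[EventRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trial_duration > 0:
            raise ValueError("trial_duration must be positive")
        self.records = sorted(self.records, key=_sort_key)

    @property
    def n_targets(self) -> int:
        return len({r.key for r in self.records} - SPECIAL_KEYS)

    @property
    def keys(self) -> list[str]:
        return sorted({r.key for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.observer_id, r.trial_id, r.condition, r.key, r.action, r.time)
                for r in self.records
            ],
            columns=CSV_COLUMNS,
        )


@dataclass
class RepairReport:
    """Counts of repairs applied by :func:`validate_and_repair`."""

    dropped_presses: int = 0
    dropped_releases: int = 0
    closed_at_trial_end: int = 0
    debounce_merges: int = 0

    @property
    def total_repairs(self) -> int:
        return (
            self.dropped_presses
            + self.dropped_releases
            + self.closed_at_trial_end
            + self.debounce_merges
        )


def read_event_log(
    path,
    *,
    trial_duration: float = 120.0,
    time_unit: str = "s",
) -> list[EventLog]:
    """Read a CSV event-log file into one :class:`EventLog` per trial.

    Parameters
    ----------
    path
        CSV file with header columns ``observer_id, trial_id, condition,
        key, action, time``.
    trial_duration
        Trial length in seconds attached to every log (the file format
        does not carry it).
    time_unit
        ``"s"`` (default) or ``"ms"``; millisecond stamps are normalised
        to seconds.

    Raises
    ------
    SchemaError
        On missing columns, unparseable or negative times, or unknown
        action labels; the message names the offending row.
    """
    if time_unit not in ("s", "ms"):
        raise ValueError(f"time_unit must be 's' or 'ms', got {time_unit!r}")
    df = pd.read_csv(path, dtype={"observer_id": str, "trial_id": str,
                                  "condition": str, "key": str, "action": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    times = pd.to_numeric(df["time"], errors="coerce")
    bad = df.index[times.isna()]
    if len(bad):
        raise SchemaError(f"{path}: unparseable time at row {bad[0] + 2}")
    if (times < 0).any():
        row = df.index[(times < 0)][0]
        raise SchemaError(f"{path}: negative time at row {row + 2}")
    bad_action = df.index[~df["action"].isin(ACTIONS)]
    if len(bad_action):
        row = bad_action[0]
        raise SchemaError(
            f"{path}: unknown action {df.loc[row, 'action']!r} at row {row + 2}"
        )

    scale = 1e-3 if time_unit == "ms" else 1.0
    df = df.assign(time=times * scale)

    logs = []
    for (obs, trial), grp in df.groupby(["observer_id", "trial_id"], sort=True):
        conditions = grp["condition"].unique()
        records = [
            EventRecord(obs, trial, row.condition, row.key, row.action, row.time)
            for row in grp.itertuples()
        ]
        logs.append(
            EventLog(
                observer_id=obs,
                trial_id=trial,
                condition=str(conditions[0]),
                trial_duration=trial_duration,
                records=records,
            )
        )
    return logs


def write_event_log(logs: list[EventLog], path) -> None:
    """Write logs to one CSV file in the canonical column order."""
    frames = [log.to_frame() for log in logs]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CSV_COLUMNS)
    )
    out.to_csv(path, index=False)


def validate_and_repair(
    log: EventLog, *, debounce_s: float = 0.0
) -> tuple[EventLog, RepairReport]:
    """Enforce per-key press/release alternation.

    Default policy: a press while the key is already down, or a release
    while it is up, is dropped; a press left open at trial end is closed at
    ``trial_duration`` (an ongoing disappearance still contributes its
    reported time).  With ``debounce_s > 0``, a release immediately
    followed by a press of the same key within the gap is merged into one
    continuous hold.  Repairs are counted, never raised.
    """
    report = RepairReport()
    by_key: dict[str, list[EventRecord]] = {}
    for rec in log.records:
        by_key.setdefault(rec.key, []).append(rec)

    repaired: list[EventRecord] = []
    for key, recs in by_key.items():
        kept: list[EventRecord] = []
        down = False
        for rec in recs:
            if rec.action == PRESS:
                if down:
                    report.dropped_presses += 1
                    continue
                if debounce_s > 0 and kept and kept[-1].action == RELEASE:
                    if rec.time - kept[-1].time < debounce_s:
                        kept.pop()  # cancel the release: continuous hold
                        report.debounce_merges += 1
                        down = True
                        continue
                down = True
                kept.append(rec)
            else:
                if not down:
                    report.dropped_releases += 1
                    continue
                down = False
                kept.append(rec)
        if down:
            last = kept[-1]
            kept.append(
                EventRecord(
                    last.observer_id,
                    last.trial_id,
                    last.condition,
                    key,
                    RELEASE,
                    log.trial_duration,
                )
            )
            report.closed_at_trial_end += 1
        repaired.extend(kept)

    out = replace(log, records=repaired)
    if report.total_repairs:
        warnings.warn(
            f"{log.observer_id}/{log.trial_id}: {report.total_repairs} repairs "
            f"({report})",
            stacklevel=2,
        )
    return out, report
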