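"""Check-in log files: a plain-CSV stand-in for the daily survey.

Columns: ``day_index,date,checked_in,behavior_value,outcome_value,
self_adherence``.  ``date`` is optional metadata (the engine keys
everything on the abstract ``day_index``); missing values are empty
fields.  Behavior values are plain numbers in the spec's units — hours
as decimals, steps as integers, times of day as minutes from midnight
(values past midnight encoded above 1440; see
:func:`nof1zones.specs.bedtime_deviation` for turning bedtimes into the
variability behavior).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Sequence, Tuple

from .engine import CheckInRecord, ExperimentState, StageDecision, ingest_day
from .specs import ExperimentSpec

__all__ = ["read_log", "write_log", "replay", "state_records"]

_COLUMNS = ["day_index", "date", "checked_in", "behavior_value", "outcome_value", "self_adherence"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(text: str, where: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse boolean {text!r}")


def read_log(path: str | Path) -> List[CheckInRecord]:
    """Read a check-in log CSV, validating the header and day ordering."""
    records: List[CheckInRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c for c in _COLUMNS if c not in reader.fieldnames]:
            raise ValueError(f"{path}: header must contain columns {', '.join(_COLUMNS)}")
        last = 0
        for i, row in enumerate(reader, start=2):
            where = f"{path}:{i}"
            day = int(row["day_index"])
            if day <= last:
                raise ValueError(f"{where}: day_index must be strictly increasing")
            last = day
            behavior = row["behavior_value"].strip()
            outcome = row["outcome_value"].strip()
            adherence = row["self_adherence"].strip()
            records.append(
                CheckInRecord(
                    day_index=day,
                    checked_in=_parse_bool(row["checked_in"], where),
                    behavior_value=float(behavior) if behavior else None,
                    outcome_value=float(outcome) if outcome else None,
                    self_adherence=int(adherence) if adherence else None,
                )
            )
    return records


def write_log(records: Sequence[CheckInRecord], path: str | Path) -> None:
    """Write records to a check-in log CSV (empty fields for missing)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.day_index,
                    "",
                    "true" if r.checked_in else "false",
                    "" if r.behavior_value is None else f"{r.behavior_value:g}",
                    "" if r.outcome_value is None else f"{r.outcome_value:g}",
                    "" if r.self_adherence is None else r.self_adherence,
                ]
            )


def state_records(state: ExperimentState) -> List[CheckInRecord]:
    """All ingested records in calendar order (restarts included)."""
    return [r for a in state.attempts for r in a.records]


def replay(
    spec: ExperimentSpec, records: Sequence[CheckInRecord]
) -> Tuple[ExperimentState, List[StageDecision]]:
    """Re-run the full ingest sequence from a record list.

    Replaying the records exported from an incrementally built state
    reproduces that state exactly; ingestion stops early if the
    experiment completes before the log ends.
    """
    state = ExperimentState.new(spec)
    decisions: List[StageDecision] = []
    for record in records:
        _, decision = ingest_day(state, record)
        decisions.append(decision)
        if state.completed:
            break
    return state, decisions
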