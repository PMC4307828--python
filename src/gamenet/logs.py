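"""Interaction logs: the record of who exchanged messages with whom.

An :class:`InteractionLog` is a sequence of time-stamped
``sender -> receiver`` exchange records, the output of the game
simulator and the input of every network measure.  Time is an integer
round index by default; ISO-8601 timestamps are accepted when reading
real deployment data (all records in a log must use one or the other).

On-disk formats: CSV with header ``time,scenario,sender,receiver,count``
and an equivalent JSON-lines dialect; :func:`read_log` auto-detects by
file extension.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import LogFormatError

__all__ = [
    "InteractionRecord",
    "InteractionLog",
    "read_log",
    "write_log_csv",
    "write_log_jsonl",
]

LOG_FIELDS = ("time", "scenario", "sender", "receiver", "count")


@dataclass(frozen=True)
class InteractionRecord:
    """One batch of communication exchanges between two players.

    ``count`` is the number of exchanges in the batch (>= 1); ``time``
    is a round index (int) or a timestamp (datetime).
    """

    time: int | datetime
    scenario: str
    sender: str
    receiver: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise LogFormatError(f"count must be >= 1, got {self.count!r}")
        if not self.sender or not self.receiver:
            raise LogFormatError("sender and receiver must be non-empty")


class InteractionLog:
    """Immutable sequence of :class:`InteractionRecord`.

    Self-exchange records (sender == receiver) are tolerated here — the
    tie-matrix builder drops them with a warning count — but the
    simulator never emits them.
    """

    def __init__(self, records: Iterable[InteractionRecord]):
        self._records: tuple[InteractionRecord, ...] = tuple(records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> InteractionRecord:
        return self._records[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionLog):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return f"InteractionLog({len(self)} records)"

    @property
    def records(self) -> tuple[InteractionRecord, ...]:
        return self._records

    def total_exchanges(self) -> int:
        """Sum of ``count`` over all records."""
        return sum(r.count for r in self._records)

    def scenarios(self) -> tuple[str, ...]:
        """Scenario labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self._records:
            seen.setdefault(r.scenario, None)
        return tuple(seen)

    def actors(self) -> frozenset[str]:
        return frozenset(x for r in self._records for x in (r.sender, r.receiver))

    def time_span(self) -> tuple[int, int]:
        """(min, max) round index over the log; error when empty."""
        if not self._records:
            raise LogFormatError("empty log has no time span")
        times = [r.time for r in self._records]
        return min(times), max(times)

    def filter(
        self,
        scenario: str | None = None,
        window: tuple | None = None,
    ) -> "InteractionLog":
        """Restrict to one scenario and/or a half-open time window [start, end)."""
        recs: Sequence[InteractionRecord] = self._records
        if scenario is not None:
            recs = [r for r in recs if r.scenario == scenario]
        if window is not None:
            start, end = window
            if start >= end:
                raise LogFormatError(f"window endpoints not ordered: {start!r} >= {end!r}")
            recs = [r for r in recs if start <= r.time < end]
        return InteractionLog(recs)


def _parse_time(raw: str, line: int) -> int | datetime:
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return datetime.fromisoformat(raw)
    except ValueError:
        raise LogFormatError(
            f"time {raw!r} is neither an integer round index nor ISO-8601", line
        ) from None


def _parse_count(raw: str, line: int) -> int:
    try:
        n = int(raw)
    except ValueError:
        raise LogFormatError(f"count {raw!r} is not an integer", line) from None
    if n < 1:
        raise LogFormatError(f"count must be a positive integer, got {n}", line)
    return n


def read_log_csv(path: str | Path) -> InteractionLog:
    """Read a log from CSV, reporting the 1-based line number on any bad row."""
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LogFormatError(f"{path}: empty file, expected header {','.join(LOG_FIELDS)}")
        if tuple(h.strip() for h in header) != LOG_FIELDS:
            raise LogFormatError(
                f"bad header {header!r}, expected {list(LOG_FIELDS)}", line=1
            )
        for row in reader:
            line = reader.line_num
            if not row:
                continue
            if len(row) != len(LOG_FIELDS):
                raise LogFormatError(
                    f"expected {len(LOG_FIELDS)} fields, got {len(row)}: {row!r}", line
                )
            time_raw, scenario, sender, receiver, count_raw = (c.strip() for c in row)
            records.append(
                InteractionRecord(
                    time=_parse_time(time_raw, line),
                    scenario=scenario,
                    sender=sender,
                    receiver=receiver,
                    count=_parse_count(count_raw, line),
                )
            )
    return InteractionLog(records)


def read_log_jsonl(path: str | Path) -> InteractionLog:
    """Read a log from JSON-lines (one record object per line)."""
    path = Path(path)
    records = []
    with path.open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise LogFormatError(f"invalid JSON: {exc}", line_no) from None
            missing = [f for f in LOG_FIELDS if f not in obj]
            if missing:
                raise LogFormatError(f"missing fields {missing}", line_no)
            time = obj["time"]
            if isinstance(time, str):
                time = _parse_time(time, line_no)
            records.append(
                InteractionRecord(
                    time=time,
                    scenario=str(obj["scenario"]),
                    sender=str(obj["sender"]),
                    receiver=str(obj["receiver"]),
                    count=_parse_count(str(obj["count"]), line_no),
                )
            )
    return InteractionLog(records)


def read_log(path: str | Path) -> InteractionLog:
    """Read a log, choosing the dialect from the file extension.

    ``.csv`` -> CSV; ``.jsonl`` / ``.json`` / ``.ndjson`` -> JSON-lines.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return read_log_csv(path)
    if suffix in (".jsonl", ".json", ".ndjson"):
        return read_log_jsonl(path)
    raise LogFormatError(f"unrecognized log extension {suffix!r} for {path}")


def _time_str(t: int | datetime) -> str:
    return t.isoformat() if isinstance(t, datetime) else str(t)


def write_log_csv(log: InteractionLog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_FIELDS)
        for r in log:
            writer.writerow([_time_str(r.time), r.scenario, r.sender, r.receiver, r.count])


def write_log_jsonl(log: InteractionLog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in log:
            t = r.time.isoformat() if isinstance(r.time, datetime) else r.time
            fh.write(
                json.dumps(
                    {
                        "time": t,
                        "scenario": r.scenario,
                        "sender": r.sender,
                        "receiver": r.receiver,
                        "count": r.count,
                    },
                    separators=(",", ":"),
                )
                + "\n"
            )
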