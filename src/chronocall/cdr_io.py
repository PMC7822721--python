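"""Reading, validation and preprocessing of call detail records (CDRs).

A call detail record is the operator-logged metadata of one telephone
event: who called, whom, when, in which direction, and for how long.
This module reproduces the standard preprocessing applied to such data
before circadian analysis:

1. keep outgoing calls only (incoming calls do not reflect a voluntary
   activity of the participant),
2. select the calendar-aligned observation window in which the greatest
   number of participants were simultaneously active,
3. retain only participants active (>= 1 outgoing call) in *every*
   calendar month of that window.

The canonical on-disk dialect is a comma-separated table with header
``person_id,timestamp,recipient_id,direction,duration_s,device_id``,
ISO-8601 timestamps and ``direction`` in ``{out, in}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTGOING = "out"
INCOMING = "in"

#: canonical column order of the CSV dialect
COLUMNS = ["person_id", "timestamp", "recipient_id", "direction", "duration_s", "device_id"]
MANDATORY_COLUMNS = COLUMNS[:-1]

#: canonical timestamp format (second resolution)
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"


class CdrError(ValueError):
    """Raised on malformed CDR input or invalid preprocessing requests."""


@dataclass(frozen=True)
class CallRecord:
    """One telephone event.

    ``duration_s`` is in seconds and must be non-negative; ``direction``
    is ``"out"`` or ``"in"``.  ``device_id`` is optional because a
    participant may own several telephones; all devices of one person
    are merged under one ``person_id`` before any filtering.
    """

    person_id: str
    timestamp: datetime
    recipient_id: str
    direction: str
    duration_s: float
    device_id: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in (OUTGOING, INCOMING):
            raise CdrError(f"direction must be 'out' or 'in', got {self.direction!r}")
        if self.duration_s < 0:
            raise CdrError(f"duration_s must be >= 0, got {self.duration_s}")


@dataclass
class CallRecordSet:
    """A person-indexed, ordered collection of call records.

    Backed by a :class:`pandas.DataFrame` in the canonical column
    order; ``timestamp`` is a datetime64 column (naive local time; the
    hour of day is taken as recorded, with no DST correction).
    """

    frame: pd.DataFrame
    n_malformed: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise CdrError(f"missing mandatory column(s): {missing}")
        self.frame = self.frame[COLUMNS].reset_index(drop=True)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterable[CallRecord]:
        for row in self.frame.itertuples(index=False):
            yield CallRecord(
                person_id=row.person_id,
                timestamp=row.timestamp.to_pydatetime(),
                recipient_id=row.recipient_id,
                direction=row.direction,
                duration_s=row.duration_s,
                device_id=None if pd.isna(row.device_id) else row.device_id,
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallRecordSet):
            return NotImplemented
        a = self.frame.fillna("").reset_index(drop=True)
        b = other.frame.fillna("").reset_index(drop=True)
        return a.equals(b)

    # -- derived views ------------------------------------------------------
    @property
    def persons(self) -> list[str]:
        """Distinct person ids, in order of first appearance."""
        return list(dict.fromkeys(self.frame["person_id"]))

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        """(earliest, latest) record timestamp."""
        if len(self.frame) == 0:
            raise CdrError("empty record set has no span")
        ts = self.frame["timestamp"]
        return ts.min(), ts.max()

    def for_person(self, person_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["person_id"] == person_id]
        if len(sub) == 0:
            raise CdrError(f"unknown person: {person_id!r}")
        return sub

    def call_hours(self, person_id: str) -> np.ndarray:
        """Fractional hour-of-day of one person's calls, in [0, 24)."""
        ts = self.for_person(person_id)["timestamp"]
        return (
            ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
        ).to_numpy(dtype=float)


@dataclass
class PreprocessSummary:
    """Cohort-level bookkeeping of the activity filter.

    Quartiles are computed over outgoing calls per *retained* person
    (linear interpolation between order statistics).
    """

    n_before: int
    n_after: int
    total_calls: int
    per_person_quartiles: tuple[float, float, float] = field(default=(np.nan,) * 3)

    def __post_init__(self) -> None:
        if self.n_after > self.n_before:
            raise CdrError("n_after cannot exceed n_before")
        q1, med, q3 = self.per_person_quartiles
        if not (np.isnan(q1) or q1 <= med <= q3):
            raise CdrError("quartiles must be ordered Q1 <= median <= Q3")

    def to_frame(self) -> pd.DataFrame:
        """Tabular export (one statistic per row)."""
        return pd.DataFrame(
            {
                "statistic": [
                    "participants_before",
                    "participants_after",
                    "total_outgoing_calls",
                    "calls_per_person_q1",
                    "calls_per_person_median",
                    "calls_per_person_q3",
                ],
                "value": [
                    self.n_before,
                    self.n_after,
                    self.total_calls,
                    *self.per_person_quartiles,
                ],
            }
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cdr(
    path: str | Path,
    delimiter: str = ",",
    column_map: dict[str, str] | None = None,
    strict: bool = False,
) -> CallRecordSet:
    """Read a delimited CDR table.

    Parameters
    ----------
    path
        Input file.
    delimiter
        Field separator of the dialect (default comma).
    column_map
        Optional mapping from canonical column names to the names used
        in the file, e.g. ``{"person_id": "caller"}``.
    strict
        If True, any malformed row aborts the read; otherwise malformed
        rows are skipped, counted in ``n_malformed`` and logged.

    Raises
    ------
    CdrError
        On a missing file, missing mandatory column, or zero parseable
        rows.
    """
    path = Path(path)
    if not path.exists():
        raise CdrError(f"no such file: {path}")
    raw = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise CdrError(f"missing mandatory column(s): {missing}")
    if "device_id" not in raw.columns:
        raw["device_id"] = ""

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    dur = pd.to_numeric(raw["duration_s"], errors="coerce")
    ok = (
        ts.notna()
        & dur.notna()
        & (dur >= 0)
        & raw["direction"].isin([OUTGOING, INCOMING])
        & (raw["person_id"] != "")
    )
    n_bad = int((~ok).sum())
    if n_bad:
        if strict:
            raise CdrError(f"{n_bad} malformed row(s) in {path} (strict mode)")
        logger.warning("skipped %d malformed row(s) in %s", n_bad, path)
    frame = pd.DataFrame(
        {
            "person_id": raw.loc[ok, "person_id"],
            "timestamp": ts[ok],
            "recipient_id": raw.loc[ok, "recipient_id"],
            "direction": raw.loc[ok, "direction"],
            "duration_s": dur[ok].astype(float),
            "device_id": raw.loc[ok, "device_id"].where(raw.loc[ok, "device_id"] != ""),
        }
    )
    if len(frame) == 0:
        raise CdrError(f"zero parseable rows in {path}")
    return CallRecordSet(frame, n_malformed=n_bad)


def write_cdr(records: CallRecordSet, path: str | Path, delimiter: str = ",") -> Path:
    """Write a record set in the canonical dialect; round-trips via
    :func:`read_cdr` bit-identically."""
    if len(records) == 0:
        raise CdrError("refusing to write an empty record set")
    path = Path(path)
    out = records.frame.copy()
    out["timestamp"] = out["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    out["device_id"] = out["device_id"].fillna("")
    out.to_csv(path, sep=delimiter, index=False)
    return path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_outgoing(records: CallRecordSet) -> CallRecordSet:
    """Keep outgoing calls only, preserving order.  Idempotent."""
    mask = records.frame["direction"] == OUTGOING
    return CallRecordSet(records.frame[mask].reset_index(drop=True))


def _active_months(frame: pd.DataFrame) -> pd.DataFrame:
    """person x calendar-month table of outgoing-call presence."""
    out = frame[frame["direction"] == OUTGOING]
    months = out["timestamp"].dt.to_period("M")
    return pd.crosstab(out["person_id"], months) > 0


def select_common_window(
    records: CallRecordSet, window_months: int
) -> tuple[pd.Period, pd.Period]:
    """Find the calendar-month-aligned interval of ``window_months``
    months during which the greatest number of persons placed at least
    one outgoing call in every month.

    Ties are broken by the earliest start month.  Returns the inclusive
    (first month, last month) pair as pandas monthly periods.
    """
    if window_months < 1:
        raise CdrError("window_months must be >= 1")
    lo, hi = records.span
    first, last = lo.to_period("M"), hi.to_period("M")
    n_months = (last - first).n + 1
    if n_months < window_months:
        raise CdrError(
            f"record span covers {n_months} month(s), shorter than the "
            f"requested {window_months}-month window"
        )
    presence = _active_months(records.frame)
    all_months = pd.period_range(first, last, freq="M")
    presence = presence.reindex(columns=all_months, fill_value=False)

    best_start, best_count = None, -1
    for i in range(n_months - window_months + 1):
        cols = all_months[i : i + window_months]
        count = int(presence[cols].all(axis=1).sum())
        if count > best_count:  # strict: earliest start wins ties
            best_start, best_count = all_months[i], count
    assert best_start is not None
    return best_start, best_start + window_months - 1


def filter_active_participants(
    records: CallRecordSet, window: tuple[pd.Period, pd.Period]
) -> tuple[CallRecordSet, PreprocessSummary]:
    """Keep persons with >= 1 outgoing call in *every* calendar month of
    ``window``; drop records outside the window.

    Returns the filtered set and a :class:`PreprocessSummary` computed
    on the result (quartiles of outgoing calls per retained person).
    A zero-retained outcome is allowed and visible as ``n_after == 0``.
    """
    start, end = window
    if end < start:
        raise CdrError("window end precedes start")
    months = pd.period_range(start, end, freq="M")
    frame = records.frame
    in_window = frame["timestamp"].dt.to_period("M").isin(months)
    windowed = frame[in_window]

    n_before = frame["person_id"].nunique()
    presence = _active_months(windowed)
    presence = presence.reindex(columns=months, fill_value=False)
    retained = presence.index[presence.all(axis=1)]

    kept = windowed[windowed["person_id"].isin(retained)].reset_index(drop=True)
    out_counts = (
        kept.loc[kept["direction"] == OUTGOING, "person_id"].value_counts()
    )
    if len(retained):
        q1, med, q3 = np.percentile(out_counts.to_numpy(dtype=float), [25, 50, 75])
        quartiles = (float(q1), float(med), float(q3))
    else:
        logger.warning("zero retained participants after activity filter")
        quartiles = (np.nan, np.nan, np.nan)
    summary = PreprocessSummary(
        n_before=int(n_before),
        n_after=int(len(retained)),
        total_calls=int(len(kept)),
        per_person_quartiles=quartiles,
    )
    return CallRecordSet(kept), summary
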