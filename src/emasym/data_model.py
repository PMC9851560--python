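"""Domain types, CSV I/O and cohort-level validation for EMA symptom diaries.

The study design is a 14-day ecological momentary assessment (EMA) protocol:
five prompts per day at fixed clock times (08:00, 11:00, 14:00, 17:00,
20:00), each collecting eight 0-100 visual-analogue symptom ratings and
three 0-3 demand Likert items whose sum is the combined demand score (0-9).
Participants who complete fewer than half of the 70 possible entries are
discarded before analysis; missing prompts are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical symptom order used everywhere downstream (matrices, CSVs).
SYMPTOMS: tuple[str, ...] = (
    "overall",
    "fatigue",
    "breathing",
    "lightheaded",
    "taste",
    "pain",
    "thinking",
    "anxious",
)

#: Demand Likert items rated 0-3 ("not at all" .. "very").
DEMANDS: tuple[str, ...] = ("physical", "mental", "emotional")

#: Scheduled prompt clock hours; prompts are 3 h apart.
PROMPT_HOURS: tuple[int, ...] = (8, 11, 14, 17, 20)
PROMPTS_PER_DAY = len(PROMPT_HOURS)
DEFAULT_N_DAYS = 14
#: Maximum possible entries over the study (14 days x 5 prompts).
MAX_ENTRIES = DEFAULT_N_DAYS * PROMPTS_PER_DAY
#: An entry belongs to a slot if made within this many hours of schedule.
SLOT_WINDOW_HOURS = 3.0

VAS_COLUMNS = tuple(f"vas_{s}" for s in SYMPTOMS)
DEMAND_COLUMNS = tuple(f"demand_{d}" for d in DEMANDS)
EMA_CSV_COLUMNS = (
    "participant_id",
    "date",
    "slot",
    "entry_time",
    *VAS_COLUMNS,
    *DEMAND_COLUMNS,
)


class EmaFormatError(ValueError):
    """Input file does not conform to the EMA CSV dialect."""


class EmaValidationError(ValueError):
    """Input rows violate EMA constraints (duplicates, bad ranges)."""


@dataclass(frozen=True)
class EmaRecord:
    """One completed diary entry."""

    participant_id: str
    timestamp: datetime
    prompt_slot: int  # 1-5
    vas: Mapping[str, float]  # symptom -> rating in [0, 100]
    demand: Mapping[str, int]  # item -> rating in {0..3}

    @property
    def combined_demand(self) -> int:
        """Sum of the three demand items, range 0-9."""
        return int(sum(self.demand[d] for d in DEMANDS))

    def __post_init__(self) -> None:
        if not 1 <= self.prompt_slot <= PROMPTS_PER_DAY:
            raise EmaValidationError(
                f"prompt_slot {self.prompt_slot} outside 1..{PROMPTS_PER_DAY}"
            )
        for s in SYMPTOMS:
            v = self.vas[s]
            if not 0 <= v <= 100:
                raise EmaValidationError(f"vas_{s}={v} outside [0, 100]")
        for d in DEMANDS:
            v = self.demand[d]
            if v not in (0, 1, 2, 3):
                raise EmaValidationError(f"demand_{d}={v} outside 0..3")


def schedule_prompts(start_date: date, n_days: int) -> list[datetime]:
    """Scheduled prompt date-times for ``n_days`` consecutive days.

    Five prompts per day at 08:00, 11:00, 14:00, 17:00 and 20:00 local
    clock time (the study is single-time-zone; times are naive).
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    out = []
    for d in range(n_days):
        day = start_date + timedelta(days=d)
        for h in PROMPT_HOURS:
            out.append(datetime(day.year, day.month, day.day, h, 0))
    return out


@dataclass
class ParticipantSeries:
    """One participant's ordered diary with its prompt schedule."""

    participant_id: str
    records: list[EmaRecord]
    start_date: date
    n_days: int = DEFAULT_N_DAYS

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.timestamp)
        times = [r.timestamp for r in self.records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise EmaValidationError(
                f"{self.participant_id}: record timestamps not strictly increasing"
            )
        seen = set()
        for r in self.records:
            key = (r.timestamp.date(), r.prompt_slot)
            if key in seen:
                raise EmaValidationError(
                    f"{self.participant_id}: duplicate entry for slot {key}"
                )
            seen.add(key)

    @property
    def schedule(self) -> list[datetime]:
        return schedule_prompts(self.start_date, self.n_days)

    @property
    def study_days(self) -> list[date]:
        return [self.start_date + timedelta(days=d) for d in range(self.n_days)]

    @property
    def n_completed(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Long-to-wide frame: one row per completed entry, VAS/demand columns."""
        rows = []
        for r in self.records:
            row = {
                "participant_id": r.participant_id,
                "date": r.timestamp.date(),
                "slot": r.prompt_slot,
                "entry_time": r.timestamp,
            }
            for s in SYMPTOMS:
                row[f"vas_{s}"] = r.vas[s]
            for d in DEMANDS:
                row[f"demand_{d}"] = r.demand[d]
            row["combined_demand"] = r.combined_demand
            rows.append(row)
        cols = list(EMA_CSV_COLUMNS) + ["combined_demand"]
        return pd.DataFrame(rows, columns=cols)

    def values(self, symptom: str) -> np.ndarray:
        """Chronologically ordered completed ratings for one symptom."""
        return np.array([r.vas[symptom] for r in self.records], dtype=float)


@dataclass
class Cohort:
    """A set of participants with optional accelerometer epoch data."""

    participants: dict[str, ParticipantSeries]
    accel: dict[str, "pd.DataFrame"] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    rejected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for pid in self.accel:
            if pid not in self.participants:
                raise EmaValidationError(f"accel data for unknown participant {pid!r}")

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants.values())

    def to_frame(self) -> pd.DataFrame:
        frames = [p.to_frame() for p in self.participants.values()]
        if not frames:
            return pd.DataFrame(columns=list(EMA_CSV_COLUMNS) + ["combined_demand"])
        return pd.concat(frames, ignore_index=True)


def _records_from_frame(df: pd.DataFrame) -> list[EmaRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            EmaRecord(
                participant_id=str(row["participant_id"]),
                timestamp=pd.Timestamp(row["entry_time"]).to_pydatetime(),
                prompt_slot=int(row["slot"]),
                vas={s: float(row[f"vas_{s}"]) for s in SYMPTOMS},
                demand={d: int(row[f"demand_{d}"]) for d in DEMANDS},
            )
        )
    return records


def load_ema(
    path,
    *,
    n_days: int = DEFAULT_N_DAYS,
    on_duplicate: str = "error",
    lateness_allowance_h: float = SLOT_WINDOW_HOURS,
) -> Cohort:
    """Read a long-format EMA CSV into a :class:`Cohort`.

    Rows with out-of-range VAS (outside 0-100) or demand values (outside
    0-3) are rejected and collected in ``cohort.rejected`` with a ``reason``
    column; ``combined_demand`` is always recomputed from the three items.
    Entries later than ``lateness_allowance_h`` after their scheduled slot
    time are rejected as slot-inconsistent.

    ``on_duplicate``: "error" raises on duplicate (participant, date, slot)
    rows; "keep_earliest" keeps the earliest entry_time and rejects the rest.
    """
    df = pd.read_csv(path)
    missing = [c for c in EMA_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise EmaFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["entry_time"] = pd.to_datetime(df["entry_time"])
    df["date"] = pd.to_datetime(df["date"]).dt.date

    reasons = pd.Series("", index=df.index, dtype=object)
    for s in SYMPTOMS:
        col = pd.to_numeric(df[f"vas_{s}"], errors="coerce")
        bad = col.isna() | (col < 0) | (col > 100)
        reasons[bad & (reasons == "")] = f"vas_{s} outside [0,100]"
    for d in DEMANDS:
        col = pd.to_numeric(df[f"demand_{d}"], errors="coerce")
        bad = col.isna() | ~col.isin([0, 1, 2, 3])
        reasons[bad & (reasons == "")] = f"demand_{d} outside 0..3"

    # slot consistency: entry within [scheduled, scheduled + allowance)
    sched_hour = df["slot"].map(dict(enumerate(PROMPT_HOURS, start=1)))
    bad_slot = df["slot"].isna() | ~df["slot"].isin(range(1, PROMPTS_PER_DAY + 1))
    reasons[bad_slot & (reasons == "")] = "invalid slot"
    sched = pd.to_datetime(df["date"].astype(str)) + pd.to_timedelta(
        sched_hour.fillna(0), unit="h"
    )
    delta_h = (df["entry_time"] - sched).dt.total_seconds() / 3600.0
    late = (~bad_slot) & ((delta_h < 0) | (delta_h >= lateness_allowance_h))
    reasons[late & (reasons == "")] = (
        f"entry_time outside slot window [scheduled, +{lateness_allowance_h}h)"
    )

    dup_mask = df.duplicated(subset=["participant_id", "date", "slot"], keep=False)
    if dup_mask.any() and (reasons[dup_mask] == "").any():
        if on_duplicate == "error":
            dups = df.loc[dup_mask, ["participant_id", "date", "slot"]]
            raise EmaValidationError(
                "duplicate (participant, date, slot) rows:\n"
                + dups.drop_duplicates().to_string(index=False)
            )
        elif on_duplicate == "keep_earliest":
            keep = (
                df[reasons == ""]
                .sort_values("entry_time")
                .duplicated(subset=["participant_id", "date", "slot"], keep="first")
            )
            extra = keep[keep].index
            reasons[extra] = "duplicate slot entry (earliest kept)"
        else:
            raise ValueError(f"unknown on_duplicate mode {on_duplicate!r}")

    rejected = df[reasons != ""].assign(reason=reasons[reasons != ""])
    good = df[reasons == ""]

    participants: dict[str, ParticipantSeries] = {}
    for pid, grp in good.groupby("participant_id", sort=True):
        start = min(grp["date"])
        participants[str(pid)] = ParticipantSeries(
            participant_id=str(pid),
            records=_records_from_frame(grp),
            start_date=start,
            n_days=n_days,
        )
    return Cohort(
        participants=participants,
        rejected=rejected.reset_index(drop=True) if len(rejected) else None,
    )


def write_ema(cohort: Cohort, path) -> None:
    """Write a cohort back to the long-format EMA CSV dialect."""
    df = cohort.to_frame().drop(columns=["combined_demand"])
    df = df.copy()
    df["entry_time"] = pd.to_datetime(df["entry_time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df["date"] = df["date"].astype(str)
    df.to_csv(path, index=False)


@dataclass
class ExclusionReport:
    """Participants removed by :func:`validate_and_filter` and why."""

    excluded: pd.DataFrame  # participant_id, reason, n_completed

    def __len__(self) -> int:
        return len(self.excluded)


def validate_and_filter(
    cohort: Cohort,
    min_entries: int = 35,
    manual_exclusions: Sequence[str] = (),
) -> tuple[Cohort, ExclusionReport]:
    """Apply the completion filter: < ``min_entries`` diary entries discards
    a participant (default 35, half the 70 possible), plus an explicit
    manual-exclusion list (e.g. protocol violations). No imputation is done
    here or anywhere downstream.
    """
    rows = []
    kept: dict[str, ParticipantSeries] = {}
    manual = set(manual_exclusions)
    for pid, series in cohort.participants.items():
        if pid in manual:
            rows.append((pid, "manual exclusion", series.n_completed))
        elif series.n_completed < min_entries:
            rows.append((pid, f"fewer than {min_entries} entries", series.n_completed))
        else:
            kept[pid] = series
    if not kept:
        import warnings

        warnings.warn("cohort empty after completion filtering", stacklevel=2)
    report = ExclusionReport(
        pd.DataFrame(rows, columns=["participant_id", "reason", "n_completed"])
    )
    accel = {pid: tr for pid, tr in cohort.accel.items() if pid in kept}
    return Cohort(participants=kept, accel=accel, meta=dict(cohort.meta)), report


@dataclass
class CompletionStats:
    total_entries: int
    n_participants: int
    pct_of_possible: float
    per_slot_counts: dict[int, int]
    median_per_participant: float
    person_days: int


def completion_stats(cohort: Cohort, n_days: int = DEFAULT_N_DAYS) -> CompletionStats:
    """Cohort completion summary: total entries, % of the possible maximum
    (n_participants x 5 x n_days), counts per prompt slot, median entries
    per participant, and person-days with any entry."""
    per_participant = [p.n_completed for p in cohort]
    total = int(sum(per_participant))
    possible = len(cohort) * n_days * PROMPTS_PER_DAY
    slot_counts = {s: 0 for s in range(1, PROMPTS_PER_DAY + 1)}
    days = 0
    for p in cohort:
        days += len({r.timestamp.date() for r in p.records})
        for r in p.records:
            slot_counts[r.prompt_slot] += 1
    return CompletionStats(
        total_entries=total,
        n_participants=len(cohort),
        pct_of_possible=100.0 * total / possible if possible else float("nan"),
        per_slot_counts=slot_counts,
        median_per_participant=float(np.median(per_participant)) if per_participant else float("nan"),
        person_days=days,
    )
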