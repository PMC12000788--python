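"""Minute-resolution sleep/nap sequences, 30-min work sequences, and
sequence-derived metrics (sleep regularity index, overlaps, gaps).

Day boundary for every grid is calendar midnight-to-midnight; periods that
span midnight are split across adjacent days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
WORK_BINS = 48  # 30-minute bins
#: work period bin ranges: 1 = midnight-8AM, 2 = 8AM-4PM, 3 = 4PM-midnight
WORK_PERIODS = {1: (0, 16), 2: (16, 32), 3: (32, 48)}


@dataclass
class BinaryDayGrid:
    """A binary per-minute (or per-30-min) series for one participant span."""

    participant: str
    start_date: Date
    bits: np.ndarray  # (n_days, bins), uint8
    resolution: int = 1  # minutes per bin
    flagged: np.ndarray = field(default=None)  # (n_days,) bool, incomplete days
    provenance: list[str] = field(default=None)  # per-day: survey|wearable|""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a days x bins matrix")
        if self.bits.shape[1] * self.resolution != MINUTES_PER_DAY:
            raise ValueError("bins per day x resolution must equal 1440")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be strictly binary")
        if self.flagged is None:
            self.flagged = np.zeros(self.n_days, dtype=bool)
        if self.provenance is None:
            self.provenance = [""] * self.n_days

    @property
    def n_days(self) -> int:
        return self.bits.shape[0]

    @property
    def dates(self) -> list[Date]:
        return [self.start_date + timedelta(days=i) for i in range(self.n_days)]

    def day_index(self, date: Date) -> int:
        idx = (date - self.start_date).days
        if not 0 <= idx < self.n_days:
            raise KeyError(f"{date} outside grid span")
        return idx


@dataclass(frozen=True)
class SriResult:
    """Sleep regularity index for one trailing window anchored at a date."""

    anchor_date: Date
    window_days: int
    value: float  # NaN when any window day is flagged


def _parse_dt(value) -> datetime | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, datetime):
        return value
    if isinstance(value, str) and value:
        return datetime.fromisoformat(value)
    if isinstance(value, pd.Timestamp):
        return value.to_pydatetime()
    return None


def _mark(bits: np.ndarray, start_date: Date, start: datetime, end: datetime) -> None:
    """Set minutes in [start, end) across the day-by-minute matrix."""
    origin = datetime.combine(start_date, datetime.min.time())
    a = int((start - origin).total_seconds() // 60)
    b = int((end - origin).total_seconds() // 60)
    total = bits.size
    a, b = max(a, 0), min(b, total)
    if a >= b:
        return
    flat = bits.reshape(-1)
    flat[a:b] = 1


def _resolve_interval(start: datetime, end: datetime) -> tuple[datetime, datetime] | None:
    """Resolve a possibly midnight-wrapped interval; None when unrecoverable."""
    if end <= start:
        end = end + timedelta(days=1)
    if end <= start or (end - start) > timedelta(hours=24):
        return None
    return start, end


def build_sleep_sequence(
    morning: pd.DataFrame,
    sleep_periods: pd.DataFrame,
    participant: str,
    start_date: Date,
    n_days: int,
) -> BinaryDayGrid:
    """Build the 1-minute sleep/nap grid for one participant.

    Survey-reported main sleep and nap intervals set their minutes to 1;
    when the survey main-sleep times are absent for a day, the wearable's
    longest sleep record attributed to that day substitutes.  A day with no
    main sleep from either source is flagged incomplete.
    """
    bits = np.zeros((n_days, MINUTES_PER_DAY), dtype=np.uint8)
    flagged = np.zeros(n_days, dtype=bool)
    provenance = [""] * n_days

    morning = morning[morning["participant"] == participant] if "participant" in morning else morning
    wear = (
        sleep_periods[sleep_periods["participant"] == participant]
        if "participant" in sleep_periods
        else sleep_periods
    )

    survey_by_date: dict[Date, pd.Series] = {}
    for _, row in morning.iterrows():
        survey_by_date[pd.Timestamp(row["date"]).date()] = row

    # wearable records attributed to the calendar date of their end time
    wear_by_date: dict[Date, list[tuple[datetime, datetime]]] = {}
    for _, row in wear.iterrows():
        s, e = _parse_dt(row["start"]), _parse_dt(row["end"])
        if s is None or e is None:
            continue
        resolved = _resolve_interval(s, e)
        if resolved is None:
            logger.warning("rejecting wearable sleep record with end before start: %s", row.to_dict())
            continue
        wear_by_date.setdefault(resolved[1].date(), []).append(resolved)

    for i in range(n_days):
        day = start_date + timedelta(days=i)
        row = survey_by_date.get(day)
        main: tuple[datetime, datetime] | None = None
        if row is not None:
            s, e = _parse_dt(row.get("main_sleep_start")), _parse_dt(row.get("main_sleep_end"))
            if s is not None and e is not None:
                main = _resolve_interval(s, e)
                if main is None:
                    logger.warning("rejecting survey main sleep for %s %s", participant, day)
                    flagged[i] = True
                else:
                    provenance[i] = "survey"
        if main is None and day in wear_by_date:
            candidates = wear_by_date[day]
            main = max(candidates, key=lambda iv: iv[1] - iv[0])
            provenance[i] = "wearable"
        if main is not None:
            _mark(bits, start_date, *main)
        else:
            flagged[i] = True
        # survey naps: "HH:MM~HH:MM|..." or ISO datetimes separated by ~
        if row is not None:
            naps = row.get("naps")
            if isinstance(naps, str) and naps:
                for token in naps.split("|"):
                    try:
                        s_raw, e_raw = token.split("~")
                        ns, ne = datetime.fromisoformat(s_raw), datetime.fromisoformat(e_raw)
                    except ValueError:
                        logger.warning("unparseable nap entry %r", token)
                        continue
                    resolved = _resolve_interval(ns, ne)
                    if resolved is None:
                        logger.warning("rejecting nap with end before start: %r", token)
                        continue
                    _mark(bits, start_date, *resolved)

    return BinaryDayGrid(participant, start_date, bits, 1, flagged, provenance)


def sri_from_bits(bits: np.ndarray) -> float:
    """SRI of a W x 1440 binary window.

    SRI = -100 + 200 / (1440 (W-1)) * sum over consecutive-day pairs of the
    number of minutes with equal sleep/wake state.
    """
    bits = np.asarray(bits)
    w = bits.shape[0]
    if w < 2:
        raise ValueError("SRI needs a window of at least 2 days")
    agree = int((bits[:-1] == bits[1:]).sum())
    return -100.0 + 200.0 * agree / (MINUTES_PER_DAY * (w - 1))


def sri(grid: BinaryDayGrid, window_days: int) -> list[SriResult]:
    """Trailing-window SRI for every anchor date with a full window.

    A flagged day anywhere inside the window yields a missing value (NaN),
    not zero.
    """
    if grid.resolution != 1:
        raise ValueError("SRI requires a 1-minute grid")
    if window_days < 2:
        raise ValueError("window_days must be >= 2")
    out: list[SriResult] = []
    for anchor in range(window_days - 1, grid.n_days):
        lo = anchor - window_days + 1
        window = slice(lo, anchor + 1)
        date = grid.start_date + timedelta(days=anchor)
        if grid.flagged[window].any():
            out.append(SriResult(date, window_days, float("nan")))
        else:
            out.append(SriResult(date, window_days, sri_from_bits(grid.bits[window])))
    return out


def build_work_grid(
    evening: pd.DataFrame, participant: str, start_date: Date, n_days: int
) -> BinaryDayGrid:
    """Build the 30-minute work grid from evening-survey ``work_bits`` strings."""
    bits = np.zeros((n_days, WORK_BINS), dtype=np.uint8)
    flagged = np.ones(n_days, dtype=bool)
    sub = evening[evening["participant"] == participant] if "participant" in evening else evening
    for _, row in sub.iterrows():
        day = pd.Timestamp(row["date"]).date()
        idx = (day - start_date).days
        if not 0 <= idx < n_days:
            continue
        raw = row.get("work_bits")
        if not isinstance(raw, str) or len(raw) != WORK_BINS or set(raw) - {"0", "1"}:
            continue
        bits[idx] = np.frombuffer(raw.encode(), dtype=np.uint8) - ord("0")
        flagged[idx] = False
    return BinaryDayGrid(participant, start_date, bits, 30, flagged)


def work_features(grid: BinaryDayGrid) -> pd.DataFrame:
    """Per-day total work hours and hours within the three 8-hour periods."""
    if grid.resolution != 30 or grid.bits.shape[1] != WORK_BINS:
        raise ValueError("work grid must have 48 bins of 30 minutes")
    rows = []
    for i, day in enumerate(grid.dates):
        if grid.flagged[i]:
            rows.append(
                {"date": day, "work_total_h": np.nan, "work_p1_h": np.nan,
                 "work_p2_h": np.nan, "work_p3_h": np.nan}
            )
            continue
        day_bits = grid.bits[i]
        periods = {
            p: 0.5 * int(day_bits[a:b].sum()) for p, (a, b) in WORK_PERIODS.items()
        }
        rows.append(
            {
                "date": day,
                "work_total_h": 0.5 * int(day_bits.sum()),
                "work_p1_h": periods[1],
                "work_p2_h": periods[2],
                "work_p3_h": periods[3],
            }
        )
    return pd.DataFrame(rows)


def sleep_work_overlap(
    sleep_grid: BinaryDayGrid, work_grid: BinaryDayGrid, max_gap_minutes: int = 48 * 60
) -> pd.DataFrame:
    """Nap-during-work minutes and sleep/shift gap minutes per day.

    ``gap_sleep_to_shift`` is the duration from the end of the last sleep
    period to the start of the day's shift; ``gap_shift_to_sleep`` from shift
    end to the start of the following sleep period.  Both are missing when
    there is no shift that day or no adjacent sleep within ``max_gap_minutes``.
    """
    if sleep_grid.start_date != work_grid.start_date or sleep_grid.n_days != work_grid.n_days:
        raise ValueError("sleep and work grids must cover identical date ranges")
    sleep_flat = sleep_grid.bits.reshape(-1)
    work_minutes = np.repeat(work_grid.bits, 30, axis=1)  # upsample to 1-min
    work_flat = work_minutes.reshape(-1)
    n = sleep_flat.size

    rows = []
    for i, day in enumerate(sleep_grid.dates):
        day_sleep = sleep_grid.bits[i]
        day_work = work_minutes[i]
        overlap = int(np.logical_and(day_sleep, day_work).sum())
        gap_in = np.nan
        gap_out = np.nan
        if work_grid.flagged[i] or day_work.sum() == 0:
            rows.append({"date": day, "nap_during_work_min": 0 if not work_grid.flagged[i] else np.nan,
                         "gap_sleep_to_shift": gap_in, "gap_shift_to_sleep": gap_out})
            continue
        shift_start = i * MINUTES_PER_DAY + int(np.argmax(day_work))
        shift_end = i * MINUTES_PER_DAY + MINUTES_PER_DAY - int(np.argmax(day_work[::-1]))
        # last sleep minute strictly before shift start
        lo = max(0, shift_start - max_gap_minutes)
        before = sleep_flat[lo:shift_start]
        if before.any():
            last = lo + len(before) - 1 - int(np.argmax(before[::-1]))
            gap_in = float(shift_start - (last + 1))
        hi = min(n, shift_end + max_gap_minutes)
        after = sleep_flat[shift_end:hi]
        if after.any():
            first = shift_end + int(np.argmax(after))
            gap_out = float(first - shift_end)
        rows.append(
            {
                "date": day,
                "nap_during_work_min": overlap,
                "gap_sleep_to_shift": gap_in,
                "gap_shift_to_sleep": gap_out,
            }
        )
    return pd.DataFrame(rows)
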