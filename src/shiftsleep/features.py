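"""Daily feature engineering and model-sample assembly.

Computes the per-day feature inventory (wearable statistics, survey fields,
sequence-derived metrics) and aggregates 4-day windows into model-ready
advice samples with response features and per-message labels.
"""

from __future__ import annotations

import logging
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

from . import sequences
from .advice import ALL_MESSAGE_IDS

logger = logging.getLogger(__name__)

FITBIT_FEATURES = [
    "hr_mean", "hr_std", "hr_entropy", "steps",
    "duration_entropy_step", "duration_entropy_non_step",
    "sleep_duration", "sleep_efficiency",
    "main_sleep_start_min", "main_sleep_end_min",
]
MORNING_FEATURES = [
    "sleep_prev_24", "nap_count", "nap_duration",
    "wake_natural", "wake_alarm", "wake_other",
    "sleep_latency", "phone_use", "brightness_sleep",
    "deep_sleep", "immediate_sleep", "fatigue_recover", "mid_awake", "sleep_satisfy",
    "alcohol_amount", "caffeine_amount",
    "caffeine_to_sleep", "bath_to_sleep",
    "sri_3", "sri_5", "sri_7",
]
MORNING_WELLBEING = [
    "alertness_morn", "happiness_morn", "energy_morn",
    "health_morn", "calmness_morn", "sleepiness_morn",
]
EVENING_WORK_FEATURES = [
    "work_today_total", "work_today_p1", "work_today_p2", "work_today_p3",
    "work_yesterday_total", "work_yesterday_p1", "work_yesterday_p2", "work_yesterday_p3",
    "work_daybefore_total", "work_daybefore_p1", "work_daybefore_p2", "work_daybefore_p3",
    "extrawork_activities", "nap_during_work",
    "gap_sleep_to_shift", "gap_shift_to_sleep",
]
EVENING_WELLBEING = [
    "alertness_eve", "happiness_eve", "energy_eve", "health_eve", "calmness_eve",
    "sleepiness_now_eve", "sleepiness_daytime", "stress", "tiredness",
]

ALL_DAILY_FEATURES = (
    FITBIT_FEATURES + MORNING_FEATURES + MORNING_WELLBEING
    + EVENING_WORK_FEATURES + EVENING_WELLBEING
)

#: features undefined on days without the triggering event / enough history
OPTIONAL_FEATURES = [
    "sri_3", "sri_5", "sri_7", "nap_during_work",
    "caffeine_to_sleep", "bath_to_sleep",
    "gap_sleep_to_shift", "gap_shift_to_sleep",
]
WELLBEING_FEATURES = MORNING_WELLBEING + EVENING_WELLBEING
SLEEP_QUALITY_FEATURES = [
    "deep_sleep", "immediate_sleep", "fatigue_recover", "mid_awake", "sleep_satisfy",
]

#: feature set used by the advice-prediction models (optional features are
#: excluded so the missing-sample exclusion rule keeps a workable fraction)
MODEL_FEATURES = [f for f in ALL_DAILY_FEATURES if f not in OPTIONAL_FEATURES]
#: feature set used for clustering: additionally withholds well-being and
#: sleep-quality metrics, which are examined only in cluster profiles
CLUSTER_FEATURES = [
    f for f in MODEL_FEATURES
    if f not in WELLBEING_FEATURES and f not in SLEEP_QUALITY_FEATURES
]


def sample_entropy(series, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    ``r`` defaults to 0.2 x SD of the series.  Returns 0 for a constant
    series and NaN when the series is too short or has no length-m template
    matches.
    """
    x = np.asarray(series, dtype=np.float32)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < m + 2:
        return float("nan")
    sd = float(x.std())
    if sd == 0.0:
        return 0.0
    if r is None:
        r = 0.2 * sd

    nt = n - m  # template count shared by both lengths (self-matches excluded)

    def _matches(length: int) -> int:
        d = np.abs(x[:nt, None] - x[None, :nt])
        for k in range(1, length):
            d = np.maximum(d, np.abs(x[k : k + nt, None] - x[None, k : k + nt]))
        return int((d <= r).sum()) - nt

    b = _matches(m)
    if b <= 0:
        return float("nan")
    a = _matches(m + 1)
    if a <= 0:
        return float("nan")
    return float(-np.log(a / b))


def _run_lengths(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lengths and boolean values of maximal runs in a boolean vector."""
    if len(mask) == 0:
        return np.array([], dtype=int), np.array([], dtype=bool)
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(mask)]))
    return ends - starts, mask[starts]


def _duration_entropy(durations: np.ndarray) -> float:
    if len(durations) == 0:
        return 0.0
    _, counts = np.unique(durations, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def segment_duration_entropy(steps) -> tuple[float, float]:
    """Information entropy of active / stationary segment-duration distributions.

    Segments are maximal runs of minutes with steps>0 (active) or steps==0
    (stationary); missing minutes count as stationary.  Returns
    ``(entropy_step, entropy_non_step)`` in nats; an absent or single-valued
    segment class scores 0.
    """
    s = np.asarray(steps, dtype=float)
    if s.size == 0:
        return float("nan"), float("nan")
    s = np.nan_to_num(s, nan=0.0)
    lengths, values = _run_lengths(s > 0)
    return (
        _duration_entropy(lengths[values]),
        _duration_entropy(lengths[~values]),
    )


def _minutes_from_midnight(ts, day: Date) -> float:
    if ts is None or (isinstance(ts, float) and np.isnan(ts)):
        return np.nan
    t = pd.Timestamp(ts)
    origin = pd.Timestamp(day)
    return float((t - origin).total_seconds() / 60.0)


def _work_hours_from_bits(raw) -> tuple[float, float, float, float] | None:
    """(total, period1, period2, period3) hours from a 48-bit work string."""
    if not isinstance(raw, str) or len(raw) != 48 or set(raw) - {"0", "1"}:
        return None
    arr = np.frombuffer(raw.encode(), dtype=np.uint8) - ord("0")
    return (
        0.5 * float(arr.sum()),
        0.5 * float(arr[:16].sum()),
        0.5 * float(arr[16:32].sum()),
        0.5 * float(arr[32:48].sum()),
    )


def _nap_minutes(raw) -> tuple[float, int]:
    if not isinstance(raw, str) or not raw:
        return 0.0, 0
    total, count = 0.0, 0
    for token in raw.split("|"):
        try:
            s_raw, e_raw = token.split("~")
            s, e = pd.Timestamp(s_raw), pd.Timestamp(e_raw)
        except ValueError:
            continue
        dur = (e - s).total_seconds() / 60.0
        if dur <= 0:
            dur += 1440.0
        if dur > 0:
            total += dur
            count += 1
    return total, count


def daily_features(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Compute the full daily feature table from the raw record sets.

    ``tables`` must hold ``participants``, ``minutes``, ``sleep_periods``,
    ``morning_survey`` and ``evening_survey`` frames with the canonical
    schemas.  Returns one row per participant-day; fields a day cannot
    support are left missing (never imputed).
    """
    participants = tables["participants"]
    minutes = tables["minutes"].copy()
    sleep_periods = tables["sleep_periods"]
    morning = tables["morning_survey"]
    evening = tables["evening_survey"]

    minutes["timestamp"] = pd.to_datetime(minutes["timestamp"])
    minutes["date"] = minutes["timestamp"].dt.date

    records: list[dict] = []
    for _, prow in participants.iterrows():
        pid = prow["participant"]
        start = pd.Timestamp(prow["start_date"]).date()
        n_days = int(prow["study_days"])

        p_min = minutes[minutes["participant"] == pid]
        p_sleep = sleep_periods[sleep_periods["participant"] == pid]
        p_morn = morning[morning["participant"] == pid].copy()
        p_eve = evening[evening["participant"] == pid].copy()
        if p_morn.duplicated("date").any():
            logger.warning("duplicate morning rows for %s; keeping last", pid)
            p_morn = p_morn.drop_duplicates("date", keep="last")
        if p_eve.duplicated("date").any():
            logger.warning("duplicate evening rows for %s; keeping last", pid)
            p_eve = p_eve.drop_duplicates("date", keep="last")
        morn_by_date = {pd.Timestamp(r["date"]).date(): r for _, r in p_morn.iterrows()}
        eve_by_date = {pd.Timestamp(r["date"]).date(): r for _, r in p_eve.iterrows()}

        sleep_grid = sequences.build_sleep_sequence(p_morn, p_sleep, pid, start, n_days)
        work_grid = sequences.build_work_grid(p_eve, pid, start, n_days)
        work_df = sequences.work_features(work_grid).set_index("date")
        overlap_df = sequences.sleep_work_overlap(sleep_grid, work_grid).set_index("date")
        sri_by = {
            w: {res.anchor_date: res.value for res in sequences.sri(sleep_grid, w)}
            for w in (3, 5, 7)
        }

        min_by_date = {d: g for d, g in p_min.groupby("date")}

        # wearable main record per day (longest, attributed to end date)
        wear_main: dict[Date, pd.Series] = {}
        for _, srow in p_sleep.iterrows():
            try:
                s_ts, e_ts = pd.Timestamp(srow["start"]), pd.Timestamp(srow["end"])
            except (TypeError, ValueError):
                continue
            day = e_ts.date()
            if day not in wear_main or (e_ts - s_ts) > (
                pd.Timestamp(wear_main[day]["end"]) - pd.Timestamp(wear_main[day]["start"])
            ):
                wear_main[day] = srow

        for i in range(n_days):
            day = start + timedelta(days=i)
            rec: dict = {"participant": pid, "date": day}
            for col in ALL_DAILY_FEATURES:
                rec[col] = np.nan

            g = min_by_date.get(day)
            if g is not None and len(g):
                hr = g["heart_rate"].to_numpy(dtype=float)
                hr_valid = hr[~np.isnan(hr)]
                if len(hr_valid):
                    rec["hr_mean"] = float(hr_valid.mean())
                    rec["hr_std"] = float(hr_valid.std(ddof=1)) if len(hr_valid) > 1 else 0.0
                    rec["hr_entropy"] = sample_entropy(hr_valid)
                st = g["steps"].to_numpy(dtype=float)
                rec["steps"] = float(np.nansum(st))
                ent_step, ent_non = segment_duration_entropy(st)
                rec["duration_entropy_step"] = ent_step
                rec["duration_entropy_non_step"] = ent_non

            mrow = morn_by_date.get(day)
            main_start = main_end = None
            if mrow is not None and pd.notna(mrow.get("main_sleep_start")) and pd.notna(
                mrow.get("main_sleep_end")
            ):
                main_start = pd.Timestamp(mrow["main_sleep_start"])
                main_end = pd.Timestamp(mrow["main_sleep_end"])
            elif day in wear_main:
                main_start = pd.Timestamp(wear_main[day]["start"])
                main_end = pd.Timestamp(wear_main[day]["end"])
            if main_start is not None:
                if main_end <= main_start:
                    main_end += pd.Timedelta(days=1)
                rec["sleep_duration"] = (main_end - main_start).total_seconds() / 60.0
                rec["main_sleep_start_min"] = _minutes_from_midnight(main_start, day)
                rec["main_sleep_end_min"] = _minutes_from_midnight(main_end, day)
            if day in wear_main:
                rec["sleep_efficiency"] = float(wear_main[day].get("efficiency", np.nan))

            if mrow is not None:
                for col in (
                    "sleep_prev_24", "sleep_latency", "phone_use", "brightness_sleep",
                    "deep_sleep", "immediate_sleep", "fatigue_recover", "mid_awake",
                    "sleep_satisfy", "alcohol_amount", "caffeine_amount",
                    *MORNING_WELLBEING,
                ):
                    if col in mrow and pd.notna(mrow[col]):
                        rec[col] = float(mrow[col])
                wake = mrow.get("wake_mode")
                if isinstance(wake, str) and wake:
                    for mode in ("natural", "alarm", "other"):
                        rec[f"wake_{mode}"] = float(wake == mode)
                nap_min, nap_cnt = _nap_minutes(mrow.get("naps"))
                rec["nap_duration"] = nap_min
                rec["nap_count"] = (
                    float(mrow["nap_count"]) if pd.notna(mrow.get("nap_count")) else float(nap_cnt)
                )
                if main_start is not None:
                    for src, dst in (
                        ("caffeine_last_time", "caffeine_to_sleep"),
                        ("bath_time", "bath_to_sleep"),
                    ):
                        if pd.notna(mrow.get(src)):
                            delta = (main_start - pd.Timestamp(mrow[src])).total_seconds() / 60.0
                            if delta >= 0:
                                rec[dst] = delta
            rec["sri_3"] = sri_by[3].get(day, np.nan)
            rec["sri_5"] = sri_by[5].get(day, np.nan)
            rec["sri_7"] = sri_by[7].get(day, np.nan)

            erow = eve_by_date.get(day)
            if erow is not None:
                if pd.notna(erow.get("extrawork_activities")):
                    rec["extrawork_activities"] = float(erow["extrawork_activities"])
                for col in EVENING_WELLBEING:
                    if col in erow and pd.notna(erow[col]):
                        rec[col] = float(erow[col])
            # the evening survey reports all three work sequences at once
            if day in work_df.index:
                wrow = work_df.loc[day]
                rec["work_today_total"] = wrow["work_total_h"]
                for p in (1, 2, 3):
                    rec[f"work_today_p{p}"] = wrow[f"work_p{p}_h"]
            if erow is not None:
                for src, tag in (
                    ("work_bits_yesterday", "yesterday"),
                    ("work_bits_daybefore", "daybefore"),
                ):
                    hours = _work_hours_from_bits(erow.get(src))
                    if hours is not None:
                        rec[f"work_{tag}_total"] = hours[0]
                        for p in (1, 2, 3):
                            rec[f"work_{tag}_p{p}"] = hours[p]
            if day in overlap_df.index:
                orow = overlap_df.loc[day]
                rec["nap_during_work"] = orow["nap_during_work_min"]
                rec["gap_sleep_to_shift"] = orow["gap_sleep_to_shift"]
                rec["gap_shift_to_sleep"] = orow["gap_shift_to_sleep"]

            records.append(rec)

    df = pd.DataFrame(records)
    return df[["participant", "date"] + ALL_DAILY_FEATURES]


def response_value(response: str) -> int:
    return {"eager": 1, "difficult": -1}.get(response, 0)


def assemble_advice_samples(
    daily: pd.DataFrame,
    advice: pd.DataFrame,
    feature_cols: list[str] | None = None,
    window: int = 4,
) -> pd.DataFrame:
    """Aggregate 4-day feature windows into model-ready advice samples.

    Each advice date contributes one row with the window mean and sample SD
    (ddof=1) of every daily feature over the ``window`` calendar days strictly
    preceding the advice date, 23 response features (most recent response to
    an advice piece containing each message: +1 eager, -1 difficult, 0
    otherwise), and one binary label per message.  Rows with any missing
    value, or with fewer than ``window`` prior days, are dropped.
    """
    if feature_cols is None:
        feature_cols = MODEL_FEATURES
    daily_idx = daily.set_index(["participant", "date"])

    advice = advice.copy()
    advice["date"] = pd.to_datetime(advice["date"]).dt.date
    advice = advice.sort_values(["participant", "date"]).reset_index(drop=True)

    last_response: dict[tuple[str, int], int] = {}
    rows = []
    n_dropped = 0
    for _, arow in advice.iterrows():
        pid, aday = arow["participant"], arow["date"]
        raw = arow["message_ids"]
        if isinstance(raw, str):
            ids = {int(tok) for tok in raw.split("|") if tok}
        else:
            ids = set(raw)

        rec: dict = {"participant": pid, "date": aday}
        window_days = [aday - timedelta(days=k) for k in range(window, 0, -1)]
        block = []
        ok = True
        for wday in window_days:
            key = (pid, wday)
            if key not in daily_idx.index:
                ok = False
                break
            block.append(daily_idx.loc[key, feature_cols].to_numpy(dtype=float))
        if ok:
            mat = np.vstack(block)
            means = mat.mean(axis=0)
            sds = mat.std(axis=0, ddof=1)
            if np.isnan(means).any() or np.isnan(sds).any():
                ok = False
            else:
                for j, col in enumerate(feature_cols):
                    rec[f"{col}__mean"] = means[j]
                    rec[f"{col}__sd"] = sds[j]
        if not ok:
            n_dropped += 1
        else:
            for mid in ALL_MESSAGE_IDS:
                rec[f"resp_{mid}"] = last_response.get((pid, mid), 0)
            for mid in ALL_MESSAGE_IDS:
                rec[f"label_{mid}"] = int(mid in ids)
            rows.append(rec)

        # history updates happen regardless of sample retention
        rv = response_value(arow.get("response", "none"))
        for mid in ids:
            last_response[(pid, mid)] = rv

    if n_dropped:
        logger.warning(
            "dropped %d/%d advice samples (incomplete 4-day windows)",
            n_dropped, len(advice),
        )
    return pd.DataFrame(rows)


def sample_feature_columns(samples: pd.DataFrame) -> list[str]:
    """Names of the model-input columns of an advice-sample frame."""
    return [
        c for c in samples.columns
        if c.endswith("__mean") or c.endswith("__sd") or c.startswith("resp_")
    ]
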