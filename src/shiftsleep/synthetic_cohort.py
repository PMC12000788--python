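"""Fully synthetic shift-worker cohort generator.

Produces the five raw record sets (participants, minute streams, sleep
records, morning/evening surveys) plus an advice log with the statistical
structure the downstream analysis assumes: rotating off/day/afternoon/
midnight shifts, shift-conditioned sleep, survey behaviors and well-being,
and a threshold-rule advice policy standing in for the physicians.

Calibration targets (population means of sleep duration, steps, heart rate,
7-day sleep regularity, selection marginals) are encoded as config defaults;
the free per-context sleep mean is solved numerically at config time so the
stationary mixture hits the configured population mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.signal import lfilter

from .advice import ALL_MESSAGE_IDS, RESPONSES

SHIFTS = ("off", "day", "afternoon", "midnight")

#: shift start minute-of-day (None = no work)
SHIFT_START = {"day": 8 * 60, "afternoon": 16 * 60, "midnight": 0}
SHIFT_BINS = {"off": (0, 0), "midnight": (0, 16), "day": (16, 32), "afternoon": (32, 48)}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PolicyRule:
    """Threshold rule for one advice message.

    Fires with probability ``noise`` regardless of the predicate, plus
    ``fire_probability`` when the window aggregate satisfies the comparison.
    A rule with ``feature=None`` is noise-only.
    """

    message_id: int
    feature: str | None = None
    aggregation: str = "mean"  # mean | sd
    comparator: str = ">"
    threshold: float = 0.0
    fire_probability: float = 0.0
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.message_id not in ALL_MESSAGE_IDS:
            raise ConfigurationError(f"invalid message_id {self.message_id}")
        if self.aggregation not in ("mean", "sd"):
            raise ConfigurationError(f"aggregation must be mean|sd, got {self.aggregation}")
        if self.comparator not in (">", "<"):
            raise ConfigurationError(f"comparator must be > or <, got {self.comparator}")
        for name in ("fire_probability", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")

    def fires(self, window_aggregates: dict, u_noise: float, u_fire: float) -> bool:
        if u_noise < self.noise:
            return True
        if self.feature is None:
            return False
        value = window_aggregates.get(f"{self.feature}__{self.aggregation}")
        if value is None or np.isnan(value):
            return False
        hit = value > self.threshold if self.comparator == ">" else value < self.threshold
        return hit and u_fire < self.fire_probability


def default_policy() -> list[PolicyRule]:
    """Default physician stand-in: one driving feature per modeled message,
    calibrated so marginal firing rates echo the published selection
    frequencies (message 20 ~ 0.50, message 21 ~ 0.28, the rest minor)."""
    rules = [
        PolicyRule(20, "sleep_satisfy", "mean", ">", 3.1, 0.73, 0.08),
        PolicyRule(21, "sleep_duration", "mean", "<", 385.0, 0.62, 0.03),
        PolicyRule(7, "brightness_sleep", "mean", ">", 25.0, 0.68, 0.02),
        PolicyRule(4, "phone_use", "mean", ">", 52.0, 0.60, 0.012),
        PolicyRule(12, "work_today_p3", "sd", ">", 3.8, 0.26, 0.012),
        PolicyRule(14, "caffeine_amount", "sd", ">", 1.45, 0.38, 0.012),
        PolicyRule(15, "nap_duration", "mean", ">", 60.0, 0.44, 0.012),
    ]
    minor_noise = {
        1: 0.025, 2: 0.02, 3: 0.015, 5: 0.02, 6: 0.012, 8: 0.03, 9: 0.025,
        10: 0.02, 13: 0.03, 16: 0.02, 17: 0.012, 18: 0.02, 19: 0.015,
        22: 0.03, 23: 0.03,
    }
    rules.extend(PolicyRule(mid, noise=v) for mid, v in minor_noise.items())
    return rules


def default_response_model() -> dict[int, tuple[float, float, float]]:
    """(none, eager, difficult) probabilities per message; extremes follow the
    published response behavior (difficult ~0.005 for message 20, ~0.20 for
    message 4, ~0.26 for message 2)."""
    model = {mid: (0.40, 0.59, 0.01) for mid in ALL_MESSAGE_IDS}
    model[20] = (0.35, 0.646, 0.004)
    model[21] = (0.40, 0.594, 0.006)
    model[7] = (0.40, 0.57, 0.03)
    model[4] = (0.35, 0.43, 0.22)
    model[2] = (0.34, 0.36, 0.30)
    for mid in (12, 13, 14, 15, 23):
        model[mid] = (0.40, 0.56, 0.04)
    return model


def _validate_dist(name: str, mean: float, sd: float) -> None:
    if sd < 0:
        raise ConfigurationError(f"{name}: negative SD ({sd})")


@dataclass
class CohortConfig:
    n_participants: int = 61
    n_hospitals: int = 2
    study_days: int = 35
    baseline_days: int = 7
    advice_per_week: float = 3.25
    advice_count_jitter: int = 2
    start_date: Date = Date(2021, 3, 1)

    # shift regime: stationary probabilities over SHIFTS and a persistence
    # weight; transition matrix = persistence*I + (1-persistence)*1 pi^T
    shift_stationary: tuple[float, float, float, float] = (0.2962, 0.2688, 0.2450, 0.1900)
    shift_persistence: float = 0.62
    rotation_bias: float = 0.35

    # sleep model: population mean/SD of main-sleep duration plus the two
    # pinned shift contexts; onset timing per current shift
    sleep_mean: float = 406.46
    sleep_sd_within: float = 150.0
    sleep_day_to_midnight: tuple[float, float] = (220.0, 60.0)
    sleep_off_to_day: tuple[float, float] = (400.0, 150.0)
    onset_jitter: float = 14.0
    nap_rate: float = 0.56
    nap_duration_mean: float = 95.0

    # behavior model
    caffeine_rate: float = 1.53
    alcohol_rate: float = 0.30
    brightness_base_mean: float = 11.7
    phone_use_mean: float = 32.0
    bath_skip_prob: float = 0.10

    # heart-rate / step model
    hr_population_mean: float = 74.87
    hr_between_sd: float = 7.0
    hr_noise_sd: float = 12.8
    hr_ar: float = 0.985
    hr_sleep_dip: float = 12.0
    steps_population_mean: float = 7545.0
    steps_population_sd: float = 4419.0

    # well-being model (Likert / continuous score baselines)
    wellbeing_sleep_debt_gain: float = 12.0
    likert_noise: float = 1.05

    policy: list[PolicyRule] = field(default_factory=default_policy)
    response_model: dict[int, tuple[float, float, float]] = field(
        default_factory=default_response_model
    )
    fallback_message: int = 20

    missingness: dict[str, float] = field(
        default_factory=lambda: {"morning": 0.10, "evening": 0.10, "fitbit": 0.045}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = np.asarray(self.shift_stationary, dtype=float)
        if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("shift_stationary must be probabilities summing to 1")
        if not 0.0 <= self.shift_persistence < 1.0:
            raise ConfigurationError("shift_persistence must be in [0,1)")
        if not 0.0 <= self.rotation_bias <= 1.0:
            raise ConfigurationError("rotation_bias must be in [0,1]")
        if self.study_days <= self.baseline_days:
            raise ConfigurationError("study_days must exceed baseline_days")
        for name, prob in self.missingness.items():
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError(f"missingness[{name}] must be in [0,1]")
        _validate_dist("sleep_sd_within", self.sleep_mean, self.sleep_sd_within)
        _validate_dist("sleep_day_to_midnight", *self.sleep_day_to_midnight)
        _validate_dist("sleep_off_to_day", *self.sleep_off_to_day)
        for name in ("onset_jitter", "hr_between_sd", "hr_noise_sd", "likert_noise",
                     "steps_population_sd", "hr_sleep_dip"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: negative SD")
        for probs3 in self.response_model.values():
            if abs(sum(probs3) - 1.0) > 1e-9 or min(probs3) < 0:
                raise ConfigurationError("response_model rows must be probability vectors")
        if not self.policy:
            raise ConfigurationError("policy must contain at least one rule")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Shift-roster chain: persistence on the diagonal, a rotation-biased
        component (off->day, day->midnight quick return, afternoon->midnight,
        midnight->off), and a correction vector solved by fixed-point
        iteration so the stationary distribution equals ``shift_stationary``.
        """
        pi = np.asarray(self.shift_stationary, dtype=float)
        pers, beta = self.shift_persistence, self.rotation_bias
        cycle = np.zeros((4, 4))
        for src, dst in (("off", "day"), ("day", "midnight"),
                         ("afternoon", "midnight"), ("midnight", "off")):
            cycle[SHIFTS.index(src), SHIFTS.index(dst)] = 1.0
        q = pi.copy()
        for _ in range(500):
            P = pers * np.eye(4) + (1 - pers) * (beta * cycle + (1 - beta) * np.tile(q, (4, 1)))
            eigval, eigvec = np.linalg.eig(P.T)
            s = np.real(eigvec[:, np.argmax(np.real(eigval))])
            s = s / s.sum()
            q = np.clip(q + (pi - s), 1e-6, None)
            q = q / q.sum()
            if np.abs(s - pi).max() < 1e-10:
                break
        return pers * np.eye(4) + (1 - pers) * (beta * cycle + (1 - beta) * np.tile(q, (4, 1)))

    def context_probabilities(self) -> dict[tuple[str, str], float]:
        pi = np.asarray(self.shift_stationary, dtype=float)
        P = self.transition_matrix
        return {
            (SHIFTS[i], SHIFTS[j]): pi[i] * P[i, j]
            for i in range(4)
            for j in range(4)
        }

    def default_sleep_mean(self) -> float:
        """Solve the non-pinned context mean so the stationary mixture of
        zero-truncated normals hits ``sleep_mean``."""
        ctx = self.context_probabilities()
        p_dm = ctx[("day", "midnight")]
        p_od = ctx[("off", "day")]
        p_rest = 1.0 - p_dm - p_od

        def trunc_mean(mu: float, sd: float) -> float:
            if sd == 0:
                return mu
            a = (0.0 - mu) / sd
            return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd))

        target = self.sleep_mean
        fixed = p_dm * trunc_mean(*self.sleep_day_to_midnight) + p_od * trunc_mean(
            *self.sleep_off_to_day
        )

        def f(mu: float) -> float:
            return fixed + p_rest * trunc_mean(mu, self.sleep_sd_within) - target

        return float(optimize.brentq(f, 100.0, 800.0))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Normal draws truncated at zero (resampled, not clipped)."""
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = out <= 0
    return out


def shift_context_sleep(
    prev_shift: str,
    cur_shift: str,
    config: CohortConfig,
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample main-sleep (onset, duration) for a shift context.

    Onset is in minutes relative to midnight of the record's calendar day
    (negative = previous evening).  The day-then-midnight context draws from
    the short-sleep regime; off-then-day from the long regime; all other
    contexts share the solved default mean.
    """
    if prev_shift not in SHIFTS or cur_shift not in SHIFTS:
        raise ConfigurationError(f"unknown shift context ({prev_shift}, {cur_shift})")
    jit = config.onset_jitter
    if cur_shift == "midnight":
        if prev_shift == "day":
            mu, sd = config.sleep_day_to_midnight
            onset = rng.normal(-5 * 60, jit, size)  # ~19:00 previous evening
        else:
            mu, sd = config.default_sleep_mean(), config.sleep_sd_within
            onset = rng.normal(9 * 60, jit * 1.4, size)  # post-shift morning sleep
    elif cur_shift == "day":
        if prev_shift == "off":
            mu, sd = config.sleep_off_to_day
        else:
            mu, sd = config.default_sleep_mean(), config.sleep_sd_within
        onset = rng.normal(-60, jit, size)  # ~23:00 previous night
    elif cur_shift == "afternoon":
        mu, sd = config.default_sleep_mean(), config.sleep_sd_within
        onset = rng.normal(45, jit * 1.2, size)  # after returning home
    else:  # off
        mu, sd = config.default_sleep_mean(), config.sleep_sd_within
        onset = rng.normal(-30, jit * 1.5, size)
    duration = _truncated_normal(rng, mu, sd, size)
    return onset, duration


@dataclass
class Cohort:
    participants: pd.DataFrame
    minutes: pd.DataFrame
    sleep_periods: pd.DataFrame
    morning_survey: pd.DataFrame
    evening_survey: pd.DataFrame
    advice: pd.DataFrame
    config: CohortConfig = None

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "participants": self.participants,
            "minutes": self.minutes,
            "sleep_periods": self.sleep_periods,
            "morning_survey": self.morning_survey,
            "evening_survey": self.evening_survey,
            "advice": self.advice,
        }


def apply_policy(
    windows: pd.DataFrame,
    policy: list[PolicyRule],
    rng: np.random.Generator,
    fallback_message: int = 20,
) -> list[frozenset[int]]:
    """Evaluate the policy on per-advice-date window aggregates.

    ``windows`` holds one row per advice event with ``<feature>__mean`` /
    ``<feature>__sd`` columns.  At most 5 messages fire per event (ties
    resolved by rule order); an event with no fired rule carries the
    fallback message.
    """
    if not policy:
        raise ConfigurationError("policy must contain at least one rule")
    events: list[frozenset[int]] = []
    for _, row in windows.iterrows():
        aggs = row.to_dict()
        fired: list[int] = []
        for rule in policy:
            if rule.fires(aggs, rng.random(), rng.random()):
                fired.append(rule.message_id)
        if not fired:
            fired = [fallback_message]
        events.append(frozenset(fired[:5]))
    return events


def _likert(rng, mu, lo, hi, sd, size=None):
    return np.clip(np.round(rng.normal(mu, sd, size)), lo, hi)


def _continuous_score(rng, mu, sd=16.0, size=None):
    return np.clip(np.round(rng.normal(mu, sd, size), 1), 1.0, 100.0)


def _fmt_minute(day: Date, minute: float) -> str:
    t = datetime.combine(day, datetime.min.time()) + timedelta(minutes=float(minute))
    return t.isoformat(timespec="minutes")


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full cohort; identical seeds give identical output."""
    cfg = config if config is not None else CohortConfig()
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    child_seeds = root.spawn(cfg.n_participants)

    default_mu = cfg.default_sleep_mean()
    P = cfg.transition_matrix
    pi = np.asarray(cfg.shift_stationary)
    n_days = cfg.study_days
    mpd = 1440

    part_rows = []
    minute_frames = []
    sleep_rows = []
    morning_rows = []
    evening_rows = []
    advice_rows = []

    # hospital sizes roughly 77/23 like the study's 47/14
    n_h1 = int(round(cfg.n_participants * 47 / 61)) if cfg.n_hospitals > 1 else cfg.n_participants

    for p_idx in range(cfg.n_participants):
        rng = np.random.default_rng(child_seeds[p_idx])
        pid = f"P{1001 + p_idx}"
        hospital = 1 if p_idx < n_h1 else 2
        part_rows.append(
            {
                "participant": pid,
                "hospital": hospital,
                "enroll_order": p_idx + 1,
                "start_date": cfg.start_date.isoformat(),
                "study_days": n_days,
            }
        )

        # --- shift roster (first-order Markov chain; 2 pre-study days so the
        # evening survey's day-before work sequence is defined from day 0) ---
        states = np.empty(n_days + 2, dtype=int)
        states[0] = rng.choice(4, p=pi)
        for d in range(1, n_days + 2):
            states[d] = rng.choice(4, p=P[states[d - 1]])
        shifts = [SHIFTS[s] for s in states[2:]]
        prev_shifts = [SHIFTS[s] for s in states[1:-1]]
        prev2_shifts = [SHIFTS[s] for s in states[:-2]]

        # --- per-day sleep (main period + naps) ---
        sleep_bits = np.zeros(n_days * mpd, dtype=np.uint8)
        main_onset = np.empty(n_days)
        main_duration = np.empty(n_days)
        nap_entries: list[list[tuple[float, float]]] = []
        for d in range(n_days):
            if shifts[d] == "midnight" and prev_shifts[d] == "day":
                mu, sd = cfg.sleep_day_to_midnight
                onset = rng.normal(-5 * 60, cfg.onset_jitter)
            elif shifts[d] == "midnight":
                mu, sd = default_mu, cfg.sleep_sd_within
                onset = rng.normal(9 * 60, cfg.onset_jitter * 1.4)
            elif shifts[d] == "day":
                if prev_shifts[d] == "off":
                    mu, sd = cfg.sleep_off_to_day
                else:
                    mu, sd = default_mu, cfg.sleep_sd_within
                onset = rng.normal(-60, cfg.onset_jitter)
            elif shifts[d] == "afternoon":
                mu, sd = default_mu, cfg.sleep_sd_within
                onset = rng.normal(45, cfg.onset_jitter * 1.2)
            else:
                mu, sd = default_mu, cfg.sleep_sd_within
                onset = rng.normal(-30, cfg.onset_jitter * 1.5)
            duration = float(_truncated_normal(rng, mu, sd))
            main_onset[d] = onset
            main_duration[d] = duration
            a = int(d * mpd + onset)
            b = int(a + duration)
            sleep_bits[max(a, 0) : max(min(b, n_days * mpd), 0)] = 1

            naps = []
            for _ in range(rng.poisson(cfg.nap_rate)):
                nd = float(np.clip(rng.gamma(1.3, cfg.nap_duration_mean / 1.3), 10, 300))
                if shifts[d] == "midnight":
                    ns = rng.uniform(16 * 60, 20 * 60)
                else:
                    ns = rng.uniform(13 * 60, 18 * 60)
                na, nb = int(d * mpd + ns), int(d * mpd + ns + nd)
                if sleep_bits[max(na, 0) : max(nb, 0)].any():
                    continue  # overlaps existing sleep; skip
                sleep_bits[max(na, 0) : min(nb, n_days * mpd)] = 1
                naps.append((ns, nd))
            nap_entries.append(naps)

        # --- minute heart rate and steps ---
        # offset compensates the sleep dip so the daily-mean population
        # average lands on hr_population_mean (~32% of minutes asleep)
        base_hr = rng.normal(
            cfg.hr_population_mean + 0.32 * cfg.hr_sleep_dip, cfg.hr_between_sd
        )
        day_eff = rng.normal(0, 3.5, n_days)
        t = np.arange(n_days * mpd)
        circadian = 2.5 * np.sin(2 * np.pi * (t - 14 * 60) / mpd)
        eps = rng.normal(0, cfg.hr_noise_sd * np.sqrt(1 - cfg.hr_ar**2), n_days * mpd)
        noise = lfilter([1.0], [1.0, -cfg.hr_ar], eps)
        hr = (
            base_hr
            + np.repeat(day_eff, mpd)
            + circadian
            - cfg.hr_sleep_dip * sleep_bits
            + noise
        )
        hr = np.clip(np.round(hr), 35, 190)

        # alternating geometric stationary/active runs, masked by wakefulness
        n_total = n_days * mpd
        p_start, p_stop = 0.20, 0.35
        n_runs = n_total // 6 + 64
        sta_lens = rng.geometric(p_start, n_runs)
        act_lens = rng.geometric(p_stop, n_runs)
        lens = np.empty(2 * n_runs, dtype=np.int64)
        lens[0::2], lens[1::2] = sta_lens, act_lens
        vals = np.zeros(2 * n_runs, dtype=bool)
        vals[1::2] = True
        active = np.repeat(vals, lens)[:n_total]
        active &= sleep_bits == 0
        steps = np.zeros(n_total)
        n_active = int(active.sum())
        if n_active:
            steps[active] = rng.gamma(2.0, 15.0, n_active)
        # rescale each day to its target total
        target_totals = np.clip(
            rng.gamma(
                (cfg.steps_population_mean / cfg.steps_population_sd) ** 2,
                cfg.steps_population_sd**2 / cfg.steps_population_mean,
                n_days,
            ),
            200,
            None,
        )
        steps_by_day = steps.reshape(n_days, mpd)
        day_sums = steps_by_day.sum(axis=1)
        scale = np.where(day_sums > 0, target_totals / np.maximum(day_sums, 1e-9), 0.0)
        steps_by_day = np.round(steps_by_day * scale[:, None])
        steps = steps_by_day.reshape(-1)

        fitbit_missing = rng.random(n_days) < cfg.missingness["fitbit"]
        morning_missing = rng.random(n_days) < cfg.missingness["morning"]
        evening_missing = rng.random(n_days) < cfg.missingness["evening"]

        origin = datetime.combine(cfg.start_date, datetime.min.time())
        timestamps = pd.date_range(origin, periods=n_days * mpd, freq="min")
        keep = np.repeat(~fitbit_missing, mpd)
        minute_frames.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "timestamp": timestamps[keep],
                    "heart_rate": hr[keep].astype(int),
                    "steps": steps[keep].astype(int),
                }
            )
        )

        # --- latent daily truth for surveys and the policy ---
        # participant habit x heavy-tailed day noise: day-level variance
        # dominates so every participant has occasional high nights
        phone_base = rng.gamma(3.0, cfg.phone_use_mean / (3.0 * np.exp(0.32)))
        bright_base = rng.gamma(2.0, cfg.brightness_base_mean / 2.0)
        truth = pd.DataFrame(index=range(n_days))
        truth["sleep_duration"] = main_duration
        truth["nap_duration"] = [sum(nd for _, nd in naps) for naps in nap_entries]
        truth["phone_use"] = np.round(phone_base * rng.lognormal(0, 0.8, n_days), 1)
        truth["brightness_sleep"] = np.clip(
            np.round(1 + bright_base * rng.lognormal(0, 0.9, n_days)), 1, 100
        )
        truth["work_today_p1"] = [
            8.0 if s == "midnight" else 0.0 for s in shifts
        ]
        truth["work_today_p3"] = [8.0 if s == "afternoon" else 0.0 for s in shifts]

        sleep_debt = np.clip(420.0 - main_duration, 0, None) / 420.0
        is_midnight = np.array([s == "midnight" for s in shifts], dtype=float)
        gain = cfg.wellbeing_sleep_debt_gain

        quality_mu = {
            "deep_sleep": 3.58, "immediate_sleep": 3.93, "fatigue_recover": 3.22,
            "mid_awake": 3.58, "sleep_satisfy": 3.23,
        }
        quality = {
            k: _likert(rng, mu - 1.3 * sleep_debt - 0.25 * is_midnight, 1, 5,
                       cfg.likert_noise, n_days)
            for k, mu in quality_mu.items()
        }
        truth["sleep_satisfy"] = quality["sleep_satisfy"]

        wb_mu_morn = {
            "alertness_morn": 45.0, "happiness_morn": 57.0, "energy_morn": 48.0,
            "health_morn": 55.5, "calmness_morn": 60.0,
        }
        wb_mu_eve = {
            "alertness_eve": 45.0, "happiness_eve": 58.0, "energy_eve": 50.0,
            "health_eve": 56.0, "calmness_eve": 61.0,
        }

        caffeine = rng.poisson(cfg.caffeine_rate, n_days)
        truth["caffeine_amount"] = caffeine

        # --- morning survey rows ---
        alcohol = rng.poisson(cfg.alcohol_rate, n_days)
        wake_modes = rng.choice(
            ["natural", "alarm", "other"], size=n_days, p=[0.4196, 0.4667, 0.1137]
        )
        for d in range(n_days):
            if morning_missing[d]:
                continue
            day = cfg.start_date + timedelta(days=d)
            naps_str = "|".join(
                f"{_fmt_minute(day, ns)}~{_fmt_minute(day, ns + nd)}"
                for ns, nd in nap_entries[d]
            )
            onset, dur = main_onset[d], main_duration[d]
            caffeine_time = onset - rng.exponential(170.0) - 30.0 if caffeine[d] else None
            bath_time = (
                onset - rng.exponential(80.0) - 20.0
                if rng.random() > cfg.bath_skip_prob
                else None
            )
            row = {
                "participant": pid,
                "date": day.isoformat(),
                "main_sleep_start": _fmt_minute(day, onset),
                "main_sleep_end": _fmt_minute(day, onset + dur),
                "naps": naps_str,
                "nap_count": len(nap_entries[d]),
                "sleep_prev_24": int(rng.random() > 0.002),
                "wake_mode": wake_modes[d],
                "sleep_latency": float(np.round(np.clip(rng.lognormal(2.55, 0.6), 1, 120), 1)),
                "phone_use": truth.loc[d, "phone_use"],
                "brightness_sleep": truth.loc[d, "brightness_sleep"],
                "deep_sleep": quality["deep_sleep"][d],
                "immediate_sleep": quality["immediate_sleep"][d],
                "fatigue_recover": quality["fatigue_recover"][d],
                "mid_awake": quality["mid_awake"][d],
                "sleep_satisfy": quality["sleep_satisfy"][d],
                "alcohol_amount": int(alcohol[d]),
                "caffeine_amount": int(caffeine[d]),
                "caffeine_last_time": _fmt_minute(day, caffeine_time)
                if caffeine_time is not None
                else "",
                "bath_time": _fmt_minute(day, bath_time) if bath_time is not None else "",
                "sleepiness_morn": _likert(
                    rng, 5.3 + 1.6 * sleep_debt[d] + 0.5 * is_midnight[d], 1, 9, 1.8
                ),
            }
            for k, mu in wb_mu_morn.items():
                row[k] = _continuous_score(
                    rng, mu - gain * sleep_debt[d] * 2.2 - 7.0 * is_midnight[d]
                )
            morning_rows.append(row)

        # --- evening survey rows ---
        extrawork = rng.random(n_days) < 0.4954
        for d in range(n_days):
            if evening_missing[d]:
                continue
            day = cfg.start_date + timedelta(days=d)

            def shift_bits(shift: str) -> str:
                bits = ["0"] * 48
                a, b = SHIFT_BINS[shift]
                for k in range(a, b):
                    bits[k] = "1"
                return "".join(bits)

            row = {
                "participant": pid,
                "date": day.isoformat(),
                "work_bits": shift_bits(shifts[d]),
                "work_bits_yesterday": shift_bits(prev_shifts[d]),
                "work_bits_daybefore": shift_bits(prev2_shifts[d]),
                "extrawork_activities": int(extrawork[d]),
                "sleepiness_now_eve": _likert(
                    rng, 5.5 + 1.2 * sleep_debt[d] + 0.4 * is_midnight[d], 1, 9, 1.65
                ),
                "sleepiness_daytime": _likert(rng, 2.5 + 0.8 * sleep_debt[d], 1, 5, 1.15),
                "stress": _likert(
                    rng, 2.85 + 0.5 * sleep_debt[d] + 0.2 * (shifts[d] != "off"), 1, 5, 1.05
                ),
                "tiredness": _likert(
                    rng, 2.4 + 0.6 * sleep_debt[d] + 0.2 * (shifts[d] != "off"), 1, 5, 0.95
                ),
            }
            for k, mu in wb_mu_eve.items():
                row[k] = _continuous_score(
                    rng, mu - gain * sleep_debt[d] * 1.8 - 5.0 * is_midnight[d]
                )
            evening_rows.append(row)

        # --- wearable sleep records ---
        for d in range(n_days):
            if fitbit_missing[d]:
                continue
            day = cfg.start_date + timedelta(days=d)
            onset, dur = main_onset[d], main_duration[d]
            drift_s, drift_e = rng.normal(0, 4, 2)
            eff = float(np.clip(np.round(rng.normal(92, 4), 1), 50, 100))
            start_ts = _fmt_minute(day, onset + drift_s)
            end_ts = _fmt_minute(day, onset + dur + drift_e)
            sleep_rows.append(
                {
                    "participant": pid,
                    "start": start_ts,
                    "end": end_ts,
                    "duration_min": round(dur + drift_e - drift_s, 1),
                    "efficiency": eff,
                }
            )

        # --- advice events ---
        n_events = int(round(cfg.advice_per_week * (cfg.study_days - cfg.baseline_days) / 7))
        if cfg.advice_count_jitter:
            n_events += int(
                rng.integers(-cfg.advice_count_jitter, cfg.advice_count_jitter + 1)
            )
        eligible = np.arange(cfg.baseline_days, cfg.study_days)
        n_events = int(np.clip(n_events, 1, len(eligible)))
        event_days = np.sort(rng.choice(eligible, size=n_events, replace=False))

        window_rows = []
        for d in event_days:
            win = truth.loc[d - 4 : d - 1]  # label-based: rows d-4..d-1 inclusive
            aggs = {}
            for col in truth.columns:
                vals = win[col].to_numpy(dtype=float)
                aggs[f"{col}__mean"] = float(vals.mean())
                aggs[f"{col}__sd"] = float(vals.std(ddof=1))
            window_rows.append(aggs)
        windows = pd.DataFrame(window_rows)
        events = apply_policy(windows, cfg.policy, rng, cfg.fallback_message)
        for d, msg_set in zip(event_days, events):
            # response follows the hardest-to-follow contained message
            primary = max(
                sorted(msg_set), key=lambda m: cfg.response_model[m][2]
            )
            resp = rng.choice(RESPONSES, p=cfg.response_model[primary])
            advice_rows.append(
                {
                    "participant": pid,
                    "date": (cfg.start_date + timedelta(days=int(d))).isoformat(),
                    "message_ids": "|".join(str(m) for m in sorted(msg_set)),
                    "response": resp,
                }
            )

    return Cohort(
        participants=pd.DataFrame(part_rows),
        minutes=pd.concat(minute_frames, ignore_index=True),
        sleep_periods=pd.DataFrame(sleep_rows),
        morning_survey=pd.DataFrame(morning_rows),
        evening_survey=pd.DataFrame(evening_rows),
        advice=pd.DataFrame(advice_rows),
        config=cfg,
    )
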