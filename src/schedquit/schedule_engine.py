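"""Deterministic generator for a 21-day gradual-reduction smoking schedule.

The schedule spreads a shrinking daily cigarette quota evenly across the
waking day.  The daily allowance starts at 85% of the baseline smoking
rate and drops by 15 percentage points every 3 days through day 12, then
by 10 points every 3 days through day 21.  Prompts within a day are
spaced at the intercigarette interval (waking minutes divided by the
day's quota), the first prompt of each day is pushed back by an extra
15 minutes per week, every prompt time snaps to the nearest quarter
hour, and prompts landing at or past bedtime are dropped.  Once the
quota reaches 3-4 cigarettes it is frozen for the remaining days.

Clock times are represented as minutes from midnight.  Overnight waking
windows (bedtime at or before wake time) are rejected as unsupported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SmokerProfile",
    "DailyQuota",
    "ScheduleDay",
    "ReductionSchedule",
    "allowed_fraction",
    "daily_quota",
    "quota_series",
    "intercigarette_interval",
    "round_to_quarter",
    "weekly_delay",
    "week_of_day",
    "generate_day",
    "generate_schedule",
    "schedule_to_frame",
    "parse_hhmm",
    "format_hhmm",
]

N_DAYS = 21
BLOCK_LENGTH = 3          # days per reduction step
QUARTER = 15              # minutes; prompt-time grid
QUOTA_FLOOR = 3           # cigarettes; quota never drops below this
QUOTA_FREEZE_AT = 4       # quota frozen once it reaches 3-4
MIN_STUDY_CPD = 10        # inclusion floor, enforced as a warning only
WEEKLY_DELAY_STEP = 15    # minutes added to the first prompt each week

# Percentage points of baseline permitted per 3-day block (days 1-3
# through days 19-21): 15-point steps for the first four blocks, then
# 10-point steps.
_BLOCK_POINTS = (85, 70, 55, 40, 30, 20, 10)


def parse_hhmm(text: str) -> int:
    """Parse an ``HH:MM`` clock string into minutes from midnight."""
    try:
        hh, mm = text.strip().split(":")
        hours, minutes = int(hh), int(mm)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"not an HH:MM clock time: {text!r}") from exc
    if not (0 <= hours <= 24 and 0 <= minutes < 60):
        raise ValueError(f"clock time out of range: {text!r}")
    return 60 * hours + minutes


def format_hhmm(minutes: int) -> str:
    """Format minutes from midnight as an ``HH:MM`` string."""
    return f"{int(minutes) // 60:02d}:{int(minutes) % 60:02d}"


@dataclass(frozen=True)
class SmokerProfile:
    """Baseline smoking rate and waking window driving schedule generation.

    Parameters
    ----------
    baseline_cpd : float
        Self-reported baseline cigarettes per day.  Values below 10 fall
        outside the intended population and trigger a warning.
    wake_time, bed_time : int
        Clock times in minutes from midnight; the waking window
        ``bed_time - wake_time`` must be positive.
    """

    baseline_cpd: float
    wake_time: int
    bed_time: int

    def __post_init__(self) -> None:
        if self.baseline_cpd <= 0:
            raise ValueError("baseline_cpd must be positive")
        if not 0 <= self.wake_time < 1440:
            raise ValueError("wake_time must lie within a single day")
        if not 0 < self.bed_time <= 1440:
            raise ValueError("bed_time must lie within a single day")
        if self.bed_time <= self.wake_time:
            raise ValueError(
                "overnight waking windows (bed_time <= wake_time) are not supported"
            )
        if self.baseline_cpd < MIN_STUDY_CPD:
            warnings.warn(
                f"baseline_cpd={self.baseline_cpd} is below the intended "
                f"minimum of {MIN_STUDY_CPD} cigarettes/day",
                stacklevel=2,
            )

    @property
    def waking_minutes(self) -> int:
        return self.bed_time - self.wake_time


@dataclass(frozen=True)
class DailyQuota:
    """Allowed fraction of baseline and the integer cigarette quota for a day."""

    day: int
    allowed_fraction: float
    quota: int
    frozen: bool


@dataclass(frozen=True)
class ScheduleDay:
    """Prompt times for one schedule day."""

    day: int
    week: int
    ici_minutes: float
    prompt_times: tuple[int, ...]


@dataclass(frozen=True)
class ReductionSchedule:
    """Complete 21-day schedule for one smoker."""

    profile: SmokerProfile
    days: tuple[ScheduleDay, ...]
    quotas: tuple[DailyQuota, ...]

    def __post_init__(self) -> None:
        if len(self.days) != N_DAYS or len(self.quotas) != N_DAYS:
            raise ValueError(f"a schedule must cover exactly {N_DAYS} days")

    def day(self, day: int) -> ScheduleDay:
        return self.days[day - 1]

    def quota(self, day: int) -> DailyQuota:
        return self.quotas[day - 1]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact .5 ties rounding up."""
    return int(math.floor(x + 0.5))


def _check_day(day: int) -> None:
    if not 1 <= day <= N_DAYS:
        raise ValueError(f"day must be in 1..{N_DAYS}, got {day}")


def allowed_points(day: int) -> int:
    """Percentage points of baseline permitted on ``day`` (85 down to 10)."""
    _check_day(day)
    return _BLOCK_POINTS[(day - 1) // BLOCK_LENGTH]


def allowed_fraction(day: int) -> float:
    """Proportion of the baseline smoking rate permitted on ``day``.

    Steps down in 3-day blocks: 0.85, 0.70, 0.55, 0.40, 0.30, 0.20, 0.10.
    The quota floor is applied separately by :func:`daily_quota`.
    """
    return allowed_points(day) / 100.0


def quota_series(baseline_cpd: float) -> tuple[DailyQuota, ...]:
    """Daily quotas for all 21 days, with the floor and freeze rules applied.

    The candidate quota is ``round_half_up(allowed_fraction * baseline)``
    clamped below at 3; on the first day the quota reaches 3-4 it is
    frozen, and all later days repeat the frozen value.
    """
    if baseline_cpd <= 0:
        raise ValueError("baseline_cpd must be positive")
    out: list[DailyQuota] = []
    frozen_value: int | None = None
    for day in range(1, N_DAYS + 1):
        points = allowed_points(day)
        fraction = points / 100.0
        if frozen_value is None:
            # points * cpd / 100 keeps exact .5 candidates exact for
            # integer baselines, so the half-up tie rule is honoured.
            candidate = round_half_up(points * baseline_cpd / 100.0)
            quota = max(candidate, QUOTA_FLOOR)
            frozen = quota <= QUOTA_FREEZE_AT
            if frozen:
                frozen_value = quota
        else:
            quota = frozen_value
            frozen = True
        if day == N_DAYS and quota > QUOTA_FREEZE_AT:
            # Very heavy baselines: 10% of baseline still exceeds the
            # 3-4 endgame band, so the final pre-quit day is capped.
            quota, frozen = QUOTA_FREEZE_AT, True
        out.append(DailyQuota(day=day, allowed_fraction=fraction, quota=quota, frozen=frozen))
    return tuple(out)


def daily_quota(profile: SmokerProfile, day: int) -> DailyQuota:
    """Quota for a single day (floor and freeze rules included)."""
    _check_day(day)
    return quota_series(profile.baseline_cpd)[day - 1]


def intercigarette_interval(waking_minutes: float, quota: int) -> float:
    """Unrounded spacing between prompts: waking minutes / daily quota."""
    if waking_minutes <= 0:
        raise ValueError("waking_minutes must be positive")
    if quota < 1:
        raise ValueError("quota must be at least 1")
    return waking_minutes / quota


def round_to_quarter(t: float) -> int:
    """Snap a clock time to the nearest quarter hour; 7.5-minute ties go up."""
    if not 0 <= t < 1440:
        raise ValueError("clock time must lie within a single day")
    return int(math.floor(t / QUARTER + 0.5)) * QUARTER


def week_of_day(day: int) -> int:
    """Schedule week (1..3) containing ``day``."""
    _check_day(day)
    return (day - 1) // 7 + 1


def weekly_delay(week: int) -> int:
    """Cumulative first-prompt delay in minutes: 15 per week, week 1 included."""
    if not 1 <= week <= 3:
        raise ValueError(f"week must be in 1..3, got {week}")
    return WEEKLY_DELAY_STEP * week


def generate_day(profile: SmokerProfile, day: int) -> ScheduleDay:
    """Generate the prompt times for one day.

    The first unrounded time is ``wake_time + weekly_delay(week)``;
    subsequent times follow at increments of the intercigarette
    interval.  Each time is snapped to the quarter-hour grid, times at
    or past bedtime are dropped, and at most ``quota`` prompts are
    emitted.  Rounding is applied to the exact arithmetic sequence, so
    no rounding error accumulates across prompts.
    """
    _check_day(day)
    quota = daily_quota(profile, day)
    week = week_of_day(day)
    ici = intercigarette_interval(profile.waking_minutes, quota.quota)
    first = profile.wake_time + weekly_delay(week)

    prompt_times: list[int] = []
    for k in range(quota.quota):
        t = first + k * ici
        if t >= min(profile.bed_time + QUARTER, 1440.0):
            break
        rounded = round_to_quarter(min(t, 1440.0 - 1e-9))
        if rounded >= profile.bed_time:
            continue
        # Quarter-grid collisions (interval shorter than the grid) keep
        # the earliest prompt so times stay strictly increasing.
        if prompt_times and rounded <= prompt_times[-1]:
            continue
        prompt_times.append(rounded)
    if not prompt_times:
        warnings.warn(
            f"day {day}: no prompt fits the waking window after the weekly delay",
            stacklevel=2,
        )
    return ScheduleDay(day=day, week=week, ici_minutes=ici, prompt_times=tuple(prompt_times))


def generate_schedule(profile: SmokerProfile) -> ReductionSchedule:
    """Generate the full 21-day reduction schedule for a smoker."""
    quotas = quota_series(profile.baseline_cpd)
    days = tuple(generate_day(profile, day) for day in range(1, N_DAYS + 1))
    return ReductionSchedule(profile=profile, days=days, quotas=quotas)


def schedule_to_frame(schedule: ReductionSchedule) -> pd.DataFrame:
    """Tabulate a schedule with one row per prompt.

    Columns: day, week, quota, ici_minutes, prompt_index, prompt_time
    (``HH:MM``).  Days whose prompts were all truncated contribute no
    rows.
    """
    rows = []
    for sched_day, quota in zip(schedule.days, schedule.quotas):
        for idx, t in enumerate(sched_day.prompt_times, start=1):
            rows.append(
                {
                    "day": sched_day.day,
                    "week": sched_day.week,
                    "quota": quota.quota,
                    "ici_minutes": sched_day.ici_minutes,
                    "prompt_index": idx,
                    "prompt_time": format_hhmm(t),
                }
            )
    columns = ["day", "week", "quota", "ici_minutes", "prompt_index", "prompt_time"]
    return pd.DataFrame(rows, columns=columns)
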