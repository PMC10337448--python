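"""Compliance statistics: expired-CO percent reduction and schedule adherence."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "COAssessment",
    "ComplianceResult",
    "AdherenceSummary",
    "co_percent_reduction",
    "classify_compliance",
    "assess_compliance",
    "schedule_adherence",
    "adherence_report",
]

DEFAULT_THRESHOLD_PCT = 50.0
DEFAULT_WINDOW_MINUTES = 5.0


@dataclass(frozen=True)
class COAssessment:
    """Expired CO (ppm) at baseline and at the last pre-quit visit."""

    co_baseline: float
    co_final: float

    def __post_init__(self) -> None:
        if self.co_baseline <= 0:
            raise ValueError("co_baseline must be positive")
        if self.co_final < 0:
            raise ValueError("co_final cannot be negative")


@dataclass(frozen=True)
class ComplianceResult:
    percent_reduction: float
    compliant: bool
    threshold: float = DEFAULT_THRESHOLD_PCT


@dataclass(frozen=True)
class AdherenceSummary:
    n_scheduled: int
    n_on_schedule: int
    prop_on_schedule: float
    n_off_schedule: int
    window_minutes: float = DEFAULT_WINDOW_MINUTES


def co_percent_reduction(a: COAssessment) -> float:
    """Percent drop in expired CO from baseline; negative if CO rose."""
    return 100.0 * (a.co_baseline - a.co_final) / a.co_baseline


def classify_compliance(percent_reduction: float, threshold: float = DEFAULT_THRESHOLD_PCT) -> ComplianceResult:
    """Classify a percent-reduction score; the threshold is inclusive."""
    return ComplianceResult(
        percent_reduction=percent_reduction,
        compliant=percent_reduction >= threshold,
        threshold=threshold,
    )


def assess_compliance(a: COAssessment, threshold: float = DEFAULT_THRESHOLD_PCT) -> ComplianceResult:
    """Convenience: percent reduction plus classification in one call."""
    return classify_compliance(co_percent_reduction(a), threshold)


def _require_sorted(values: Sequence[float], label: str) -> None:
    for prev, cur in zip(values, values[1:]):
        if cur < prev:
            raise ValueError(f"{label} must be sorted in ascending order")


def schedule_adherence(
    prompts: Sequence[float],
    events: Sequence[float],
    window: float = DEFAULT_WINDOW_MINUTES,
) -> AdherenceSummary:
    """Match smoked-cigarette events to scheduled prompts.

    Events are matched one-to-one to prompts, closest pairs first, within
    a symmetric ``window`` (boundary inclusive).  Matched events count as
    on-schedule; unmatched events are off-schedule.  Prompts without a
    matched event are simply unused: missing a scheduled cigarette is not
    a violation.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    prompts = list(prompts)
    events = list(events)
    _require_sorted(prompts, "prompts")
    _require_sorted(events, "events")

    candidates = sorted(
        (abs(e - p), ei, pi)
        for ei, e in enumerate(events)
        for pi, p in enumerate(prompts)
        if abs(e - p) <= window
    )
    matched_events: set[int] = set()
    matched_prompts: set[int] = set()
    for _, ei, pi in candidates:
        if ei not in matched_events and pi not in matched_prompts:
            matched_events.add(ei)
            matched_prompts.add(pi)

    n_on = len(matched_events)
    n_scheduled = len(prompts)
    return AdherenceSummary(
        n_scheduled=n_scheduled,
        n_on_schedule=n_on,
        prop_on_schedule=n_on / n_scheduled if n_scheduled else 0.0,
        n_off_schedule=len(events) - n_on,
        window_minutes=window,
    )


def adherence_report(
    events: pd.DataFrame,
    window: float = DEFAULT_WINDOW_MINUTES,
) -> pd.DataFrame:
    """Per-participant adherence from an event table.

    ``events`` needs columns ``participant_id``, ``timestamp`` (minutes)
    and ``kind`` in {"scheduled_prompt", "smoked"}.
    """
    required = {"participant_id", "timestamp", "kind"}
    if not required.issubset(events.columns):
        raise ValueError(f"event table needs columns {sorted(required)}")
    bad = set(events["kind"].unique()) - {"scheduled_prompt", "smoked"}
    if bad:
        raise ValueError(f"unknown event kinds: {sorted(bad)}")

    rows = []
    for pid, group in events.sort_values("timestamp").groupby("participant_id"):
        prompts = group.loc[group["kind"] == "scheduled_prompt", "timestamp"].tolist()
        smoked = group.loc[group["kind"] == "smoked", "timestamp"].tolist()
        summary = schedule_adherence(prompts, smoked, window=window)
        rows.append(
            {
                "participant_id": pid,
                "n_scheduled": summary.n_scheduled,
                "n_on_schedule": summary.n_on_schedule,
                "prop_on_schedule": summary.prop_on_schedule,
                "n_off_schedule": summary.n_off_schedule,
                "window_minutes": summary.window_minutes,
            }
        )
    return pd.DataFrame(rows)
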