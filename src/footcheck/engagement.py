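"""Usage-log analytics: foot-check counting, weekly rates, and the
three-way engagement classification (continuous / temporary / failed)
observed over a 12-week self-monitoring study.

A log holds timestamped events of two kinds: generic ``app_interaction``
events and ``foot_check`` events (a photo plus analysis, carrying the
measured relative wound size).  Engagement is classified from foot-check
events only: continuous use means at least 20 foot checks over the
study, fewer than 10 means engagement failed, and everything between
(10-19 inclusive) counts as temporary engagement.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

CONTINUOUS_MIN = 20
FAILED_BELOW = 10
DEFAULT_STUDY_DAYS = 84


@dataclass(frozen=True)
class EngagementEvent:
    timestamp: dt.datetime
    kind: str
    relative_size_pct: float | None = None

    def __post_init__(self):
        if self.kind not in ("app_interaction", "foot_check"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if (self.relative_size_pct is not None) != (self.kind == "foot_check"):
            raise ValueError(
                "relative_size_pct must be present exactly for foot_check events"
            )


@dataclass(frozen=True)
class EngagementLog:
    events: tuple
    study_start: dt.datetime | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.timestamp))
        )

    def __len__(self):
        return len(self.events)


@dataclass(frozen=True)
class EngagementSummary:
    total_foot_checks: int
    study_days: int
    weekly_rate: float
    classification: str


def count_foot_checks(log: EngagementLog, window=None) -> int:
    """Number of foot-check events, optionally within [start, end]."""
    events = [e for e in log.events if e.kind == "foot_check"]
    if window is None:
        return len(events)
    start, end = window
    if start > end:
        raise ValueError(f"window start {start} is after end {end}")
    return sum(1 for e in events if start <= e.timestamp <= end)


def weekly_rate(log: EngagementLog, study_days: int) -> float:
    """Foot checks per week over a study of ``study_days`` days."""
    if study_days <= 0:
        raise ValueError("study_days must be positive")
    return count_foot_checks(log) / (study_days / 7.0)


def classify_engagement(log: EngagementLog, study_days: int = DEFAULT_STUDY_DAYS) -> str:
    """Classify a usage log as continuous, temporary or failed engagement.

    Total function of the foot-check count: >= 20 continuous, < 10
    failed, 10-19 temporary.
    """
    if study_days <= 0:
        raise ValueError("study_days must be positive")
    total = count_foot_checks(log)
    if total >= CONTINUOUS_MIN:
        return "continuous"
    if total < FAILED_BELOW:
        return "failed"
    return "temporary"


def summarize_engagement(
    log: EngagementLog, study_days: int = DEFAULT_STUDY_DAYS
) -> EngagementSummary:
    return EngagementSummary(
        total_foot_checks=count_foot_checks(log),
        study_days=study_days,
        weekly_rate=weekly_rate(log, study_days),
        classification=classify_engagement(log, study_days),
    )
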