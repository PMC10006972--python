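"""Progress series, goal logic, outlier flagging and feedback tiers.

The progress graph starts at 100% (the baseline foot check) and tracks
relative wound size over time.  A star marks the goal of a 50%
reduction within 4 weeks of baseline — a milestone that is predictive
of complete healing over an extended 12-week horizon.  Occasional
analysis errors can produce wildly inflated values (hundreds to
thousands of percent) that wreck the graph's scale, so checks can be
flagged as outliers and excluded from display; feedback messages are
tiered on the trend of the trusted points.
"""

from __future__ import annotations

import datetime as dt
import statistics
from dataclasses import dataclass, field, replace

from .measurement import FootCheck, relative_size

GOAL_MESSAGE = "You’ve Reached Your Goal!"

_MESSAGES = {
    "goal_reached": GOAL_MESSAGE,
    "improving": "Great progress — your wound is getting smaller.",
    "steady": "Your wound size is holding steady. Keep up your care routine.",
    "worsening": "Your wound looks larger than last time. Consider seeing your podiatrist.",
    "check_photo": "This result looks unreliable. Please retake the photo and redo the analysis.",
}


class TrackingError(ValueError):
    pass


@dataclass(frozen=True)
class GoalSpec:
    """Target reduction (percent of baseline) within a horizon.

    Defaults encode the clinical milestone: 50% reduction within 28
    days, predictive of healing within 84 days.
    """

    reduction_pct: float = 50.0
    horizon_days: int = 28
    prediction_horizon_days: int = 84

    def __post_init__(self):
        if not (0 < self.reduction_pct < 100):
            raise ValueError("reduction_pct must lie strictly between 0 and 100")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")


@dataclass(frozen=True)
class GoalStatus:
    reached: bool
    reached_date: dt.datetime | None
    star_position: tuple  # (date, percent): where the star sits on the graph
    predicts_healing: bool  # informational only, not a clinical claim


@dataclass(frozen=True)
class FeedbackResult:
    tier: str
    message: str
    badge: bool


@dataclass(frozen=True)
class ProgressSeries:
    """Time-ordered foot checks with baseline normalisation.

    Immutable: ``append_check`` returns a new series.  The first check
    fixes the baseline fraction and is reported as exactly 100%.
    """

    checks: tuple = ()
    baseline_fraction: float | None = None
    baseline_date: dt.datetime | None = None
    goal: GoalSpec = field(default_factory=GoalSpec)
    outlier_threshold_pct: float = 300.0

    def __post_init__(self):
        object.__setattr__(self, "checks", tuple(self.checks))

    def __len__(self):
        return len(self.checks)


def append_check(series: ProgressSeries, check: FootCheck) -> ProgressSeries:
    """Append a check, normalising it against the series baseline.

    The first check appended becomes the baseline (relative size exactly
    100).  Timestamps must be non-decreasing.  Outlier flags for the
    whole series are recomputed after the append.
    """
    if series.checks and check.timestamp < series.checks[-1].timestamp:
        raise TrackingError(
            f"check at {check.timestamp} is earlier than the last check "
            f"({series.checks[-1].timestamp})"
        )
    if not series.checks:
        if check.ulcer_fraction <= 0:
            raise TrackingError(
                "baseline foot check shows no ulcer; relative scale undefined"
            )
        first = replace(check, relative_size_pct=100.0, outlier=False)
        return replace(
            series,
            checks=(first,),
            baseline_fraction=check.ulcer_fraction,
            baseline_date=check.timestamp,
        )
    rel = relative_size(check.ulcer_fraction, series.baseline_fraction)
    new = replace(series, checks=series.checks + (replace(check, relative_size_pct=rel),))
    return flag_outliers(new)


def flag_outliers(series: ProgressSeries) -> ProgressSeries:
    """Flag implausible checks: relative size above the absolute
    threshold (default 300%) or above 5x the series median.  The
    baseline check is never flagged."""
    if not series.checks:
        return series
    rels = [c.relative_size_pct for c in series.checks]
    med = statistics.median(rels)
    new_checks = []
    for i, c in enumerate(series.checks):
        if i == 0:
            new_checks.append(replace(c, outlier=False))
            continue
        r = c.relative_size_pct
        is_out = r > series.outlier_threshold_pct or r > 5.0 * med
        new_checks.append(replace(c, outlier=bool(is_out)))
    return replace(series, checks=tuple(new_checks))


def goal_status(series: ProgressSeries, at_date=None) -> GoalStatus:
    """Whether the reduction goal was met within the horizon.

    Reached iff some non-outlier check dated within ``horizon_days`` of
    baseline (and not after ``at_date``, when given) has relative size
    at or below 100 - reduction_pct; attaining the threshold exactly
    counts.  The star marks (baseline + horizon, 100 - reduction).
    """
    if not series.checks:
        raise TrackingError("goal status needs a series with a baseline")
    goal = series.goal
    deadline = series.baseline_date + dt.timedelta(days=goal.horizon_days)
    target = 100.0 - goal.reduction_pct
    reached_date = None
    for c in series.checks:
        if c.outlier or c.timestamp > deadline:
            continue
        if at_date is not None and c.timestamp > at_date:
            continue
        if c.relative_size_pct <= target:
            reached_date = c.timestamp
            break
    return GoalStatus(
        reached=reached_date is not None,
        reached_date=reached_date,
        star_position=(deadline, target),
        predicts_healing=reached_date is not None,
    )


def graph_points(series: ProgressSeries, exclude_outliers: bool = True) -> list:
    """(date, percent) points for the progress graph, time-ordered.

    The baseline point is always included; outlier-flagged checks are
    dropped when ``exclude_outliers``.
    """
    pts = []
    for i, c in enumerate(series.checks):
        if exclude_outliers and c.outlier and i > 0:
            continue
        pts.append((c.timestamp, c.relative_size_pct))
    return pts


def select_feedback(series: ProgressSeries) -> FeedbackResult:
    """Pick the feedback tier for the latest check.

    An outlier-flagged or geometrically implausible latest check asks
    the user to retake the photo; otherwise reaching the goal wins, and
    failing that the trend between the two latest trusted checks decides
    (a +/-5 percentage-point band counts as steady).
    """
    if not series.checks:
        raise TrackingError("feedback needs at least one check")
    latest = series.checks[-1]
    if latest.outlier or latest.flags.any_geometric:
        return FeedbackResult("check_photo", _MESSAGES["check_photo"], badge=False)
    if goal_status(series).reached:
        return FeedbackResult("goal_reached", _MESSAGES["goal_reached"], badge=True)
    trusted = [c for c in series.checks if not c.outlier]
    if len(trusted) < 2:
        return FeedbackResult("steady", _MESSAGES["steady"], badge=False)
    r, r_prev = trusted[-1].relative_size_pct, trusted[-2].relative_size_pct
    if r < r_prev - 5:
        tier = "improving"
    elif r > r_prev + 5:
        tier = "worsening"
    else:
        tier = "steady"
    return FeedbackResult(tier, _MESSAGES[tier], badge=False)
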