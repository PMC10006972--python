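"""Reference-free wound measurement.

No ruler or sticker is in the photo, so absolute (cm^2) area is not
recoverable.  Instead the foot's own pixel area is the scale: the
quantity of interest is the ulcer/foot pixel ratio, and wound size is
reported as a percentage of that ratio at the first (baseline) foot
check.  Because both areas rescale together, the metric is invariant to
camera distance and image resolution:

    relative_t = 100 * (ulcer/foot)_t / (ulcer/foot)_0
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

from .segmentation import QualityFlags, SegmentationResult


class MeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class FootCheck:
    """One timestamped wound measurement."""

    timestamp: dt.datetime
    foot_area_px: int
    ulcer_area_px: int
    ulcer_fraction: float
    relative_size_pct: float | None = None
    note: str = ""
    flags: QualityFlags = QualityFlags()
    outlier: bool = False

    def __post_init__(self):
        if self.foot_area_px <= 0:
            raise MeasurementError("foot area must be positive")
        if not (0.0 <= self.ulcer_fraction <= 1.0):
            raise MeasurementError("ulcer_fraction must lie in [0, 1]")
        if self.relative_size_pct is not None and self.relative_size_pct < 0:
            raise MeasurementError("relative_size_pct must be >= 0")


def measure(result: SegmentationResult, timestamp, note: str = "") -> FootCheck:
    """Turn a segmentation into a foot check (relative size still unset).

    Areas count region-labelled pixels only; watershed-line pixels are
    excluded by construction of the masks.
    """
    foot_area = int(result.foot_mask.sum())
    if foot_area == 0:
        raise MeasurementError("cannot measure from an empty foot mask")
    ulcer_area = int(result.ulcer_mask.sum())
    return FootCheck(
        timestamp=timestamp,
        foot_area_px=foot_area,
        ulcer_area_px=ulcer_area,
        ulcer_fraction=ulcer_area / foot_area,
        note=note,
        flags=result.flags,
    )


def relative_size(fraction: float, baseline_fraction: float) -> float:
    """Wound size as a percentage of the baseline ulcer/foot fraction."""
    if baseline_fraction <= 0:
        raise MeasurementError(
            "baseline fraction must be positive: the first foot check must "
            "show the ulcer (relative scale undefined otherwise)"
        )
    if fraction < 0:
        raise MeasurementError("fraction must be >= 0")
    return 100.0 * fraction / baseline_fraction


def with_relative(check: FootCheck, baseline_fraction: float) -> FootCheck:
    return replace(
        check, relative_size_pct=relative_size(check.ulcer_fraction, baseline_fraction)
    )
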