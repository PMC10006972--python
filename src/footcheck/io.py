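"""File formats: PNG images and masks, scribble JSON, and the two CSV
logs (foot checks; app interactions).

Canonical image output is PNG so synthetic pipelines round-trip
bit-exactly; JPEG is accepted on read.  CSVs are RFC 4180 with UTF-8
and ISO-8601 timestamps (naive timestamps are taken as local time).
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .engagement import EngagementEvent, EngagementLog
from .marking import DEFAULT_STROKE_RADIUS, LABELS, ScribbleSet, Stroke
from .measurement import FootCheck
from .segmentation import QualityFlags
from .tracking import GoalSpec

logger = logging.getLogger("footcheck")

CHECK_LOG_HEADER = [
    "timestamp",
    "foot_area_px",
    "ulcer_area_px",
    "ulcer_fraction",
    "relative_size_pct",
    "outlier",
    "flags",
    "note",
]

_FLAG_NAMES = (
    "foot_touches_border",
    "foot_area_implausible",
    "ulcer_touches_foot_edge",
    "ulcer_empty",
)


@dataclass(frozen=True)
class RunConfig:
    """Tool-wide knobs: goal definition, outlier threshold, stroke
    geometry, graph behaviour.  Precedence: CLI flags > config file >
    these defaults."""

    goal: GoalSpec = field(default_factory=GoalSpec)
    outlier_threshold_pct: float = 300.0
    stroke_radius: int = DEFAULT_STROKE_RADIUS
    exclude_outliers: bool = True
    seed: int | None = None
    verbosity: str = "INFO"


def load_config(path) -> RunConfig:
    """Flat ``key = value`` config file; unknown keys are rejected."""
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (part.strip() for part in line.split("=", 1))
        values[key] = val
    goal = GoalSpec(
        reduction_pct=float(values.pop("goal_reduction_pct", 50.0)),
        horizon_days=int(values.pop("goal_horizon_days", 28)),
        prediction_horizon_days=int(values.pop("prediction_horizon_days", 84)),
    )
    kwargs = {}
    if "outlier_threshold_pct" in values:
        kwargs["outlier_threshold_pct"] = float(values.pop("outlier_threshold_pct"))
    if "stroke_radius" in values:
        kwargs["stroke_radius"] = int(values.pop("stroke_radius"))
    if "exclude_outliers" in values:
        kwargs["exclude_outliers"] = values.pop("exclude_outliers").lower() in (
            "1",
            "true",
            "yes",
        )
    if "seed" in values:
        kwargs["seed"] = int(values.pop("seed"))
    if "verbosity" in values:
        kwargs["verbosity"] = values.pop("verbosity")
    if values:
        raise ValueError(f"unknown config keys: {sorted(values)}")
    return RunConfig(goal=goal, **kwargs)


# ---------------------------------------------------------------------------
# images and masks

def read_image(path) -> np.ndarray:
    """Read PNG/JPEG as (H, W, 3) uint8; greyscale promoted, alpha dropped."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            return np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise FileNotFoundError(f"image file not found: {path}") from None
    except UnidentifiedImageError as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from None


def write_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(Path(path))


def write_mask(mask: np.ndarray, path) -> None:
    """Boolean mask as single-channel PNG, 0/255."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(Path(path))


def read_mask(path) -> np.ndarray:
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("L")) >= 128


# ---------------------------------------------------------------------------
# scribble JSON

def save_scribbles(scribbles: ScribbleSet, path) -> None:
    doc = {
        "image_height": scribbles.image_height,
        "image_width": scribbles.image_width,
        "strokes": [
            {
                "label": s.label,
                "radius": s.radius,
                "points": [[r, c] for r, c in s.points],
            }
            for s in scribbles.strokes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_scribbles(path) -> ScribbleSet:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except FileNotFoundError:
        raise FileNotFoundError(f"scribble file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON: {exc}") from None
    for key in ("image_height", "image_width", "strokes"):
        if key not in doc:
            raise ValueError(f"{path}: missing field {key!r}")
    strokes = []
    for i, s in enumerate(doc["strokes"]):
        for key in ("label", "points"):
            if key not in s:
                raise ValueError(f"{path}: stroke {i}: missing field {key!r}")
        if s["label"] not in LABELS:
            raise ValueError(
                f"{path}: stroke {i}: invalid label {s['label']!r} "
                f"(expected one of {list(LABELS)})"
            )
        strokes.append(
            Stroke(
                label=s["label"],
                points=tuple((int(r), int(c)) for r, c in s["points"]),
                radius=int(s.get("radius", DEFAULT_STROKE_RADIUS)),
            )
        )
    return ScribbleSet(
        strokes=tuple(strokes),
        image_height=int(doc["image_height"]),
        image_width=int(doc["image_width"]),
    )


# ---------------------------------------------------------------------------
# foot-check log CSV

def _format_ts(ts: dt.datetime) -> str:
    return ts.isoformat()


def _parse_ts(text: str) -> dt.datetime:
    return dt.datetime.fromisoformat(text)


def append_check_log(path, check: FootCheck) -> None:
    """Append one foot check as a CSV row, writing the header on first use."""
    path = Path(path)
    new = not path.exists() or path.stat().st_size == 0
    flags = "|".join(n for n in _FLAG_NAMES if getattr(check.flags, n))
    row = [
        _format_ts(check.timestamp),
        str(check.foot_area_px),
        str(check.ulcer_area_px),
        repr(check.ulcer_fraction),
        "" if check.relative_size_pct is None else repr(check.relative_size_pct),
        "true" if check.outlier else "false",
        flags,
        check.note,
    ]
    with path.open("a", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(CHECK_LOG_HEADER)
        writer.writerow(row)


def read_checks(path) -> list:
    """All foot checks from a check-log CSV, sorted by timestamp."""
    path = Path(path)
    checks = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return []
        if header != CHECK_LOG_HEADER:
            raise ValueError(f"{path}:1: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CHECK_LOG_HEADER):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(CHECK_LOG_HEADER)} fields, "
                    f"got {len(row)}"
                )
            try:
                flagset = set(filter(None, row[6].split("|")))
                checks.append(
                    FootCheck(
                        timestamp=_parse_ts(row[0]),
                        foot_area_px=int(row[1]),
                        ulcer_area_px=int(row[2]),
                        ulcer_fraction=float(row[3]),
                        relative_size_pct=float(row[4]) if row[4] else None,
                        outlier=row[5].lower() == "true",
                        flags=QualityFlags(**{n: n in flagset for n in _FLAG_NAMES}),
                        note=row[7],
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    stamps = [c.timestamp for c in checks]
    if stamps != sorted(stamps):
        logger.warning("check log %s has out-of-order rows; sorting", path)
        checks.sort(key=lambda c: c.timestamp)
    return checks


def read_check_log(path) -> EngagementLog:
    """Check-log CSV as an engagement log of foot_check events."""
    checks = read_checks(path)
    events = tuple(
        EngagementEvent(
            timestamp=c.timestamp,
            kind="foot_check",
            relative_size_pct=(
                float("nan") if c.relative_size_pct is None else c.relative_size_pct
            ),
        )
        for c in checks
    )
    return EngagementLog(events=events)


# ---------------------------------------------------------------------------
# interaction log CSV (timestamp,event)

def write_interaction_log(path, log: EngagementLog) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp", "event"])
        for e in log.events:
            writer.writerow([_format_ts(e.timestamp), e.kind])


def write_foot_check_log(path, log: EngagementLog) -> None:
    """The study's second log file: timestamp and wound size per foot check."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp", "relative_size_pct"])
        for e in log.events:
            if e.kind == "foot_check":
                writer.writerow([_format_ts(e.timestamp), repr(e.relative_size_pct)])


def read_foot_check_log(path) -> EngagementLog:
    path = Path(path)
    events = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return EngagementLog(events=())
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                events.append(
                    EngagementEvent(
                        timestamp=_parse_ts(row[0]),
                        kind="foot_check",
                        relative_size_pct=float(row[1]),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    return EngagementLog(events=tuple(events))
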