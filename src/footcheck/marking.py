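"""User scribbles and their conversion to watershed seed markers.

A foot check asks the user to draw a handful of labelled strokes on the
photo: a line around the foot (background), lines inside the foot (foot)
and a line or tap inside the wound (ulcer).  Each stroke is an ordered
polyline in pixel coordinates; rasterising the set produces the marker
grid that seeds the watershed flood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABELS = ("background", "foot", "ulcer")

#: marker-grid codes; 0 means "no marker here"
MARKER_CODES = {"background": 1, "foot": 2, "ulcer": 3}
DEFAULT_STROKE_RADIUS = 2


@dataclass(frozen=True)
class Stroke:
    """One labelled polyline stroke.

    Parameters
    ----------
    label : str
        One of ``background``, ``foot``, ``ulcer``.
    points : tuple of (row, col)
        Ordered pixel coordinates, 0-based, origin top-left.  A single
        point models a tap.
    radius : int
        Disc half-width the rasterised polyline is dilated by.  Default 2
        px approximates a stylus tip at phone resolution.
    """

    label: str
    points: tuple
    radius: int = DEFAULT_STROKE_RADIUS

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(
                f"unknown stroke label {self.label!r}; expected one of {LABELS}"
            )
        pts = tuple((int(r), int(c)) for r, c in self.points)
        if len(pts) < 1:
            raise ValueError("a stroke needs at least one point")
        if self.radius < 0:
            raise ValueError("stroke radius must be >= 0")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class ScribbleSet:
    """All strokes drawn for one image, plus the image geometry."""

    strokes: tuple
    image_height: int
    image_width: int

    def __post_init__(self):
        object.__setattr__(self, "strokes", tuple(self.strokes))
        for i, s in enumerate(self.strokes):
            for r, c in s.points:
                if not (0 <= r < self.image_height and 0 <= c < self.image_width):
                    raise ValueError(
                        f"stroke {i}: point ({r}, {c}) outside "
                        f"{self.image_height}x{self.image_width} image"
                    )

    def with_label(self, label):
        return [s for s in self.strokes if s.label == label]


@dataclass(frozen=True)
class Issue:
    """One validation problem: kind, offending stroke index (or None), message."""

    kind: str
    stroke_index: int | None
    message: str


def bresenham_line(p0, p1):
    """Integer pixels of the Bresenham segment from p0 to p1, inclusive."""
    r0, c0 = p0
    r1, c1 = p1
    pixels = []
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r0 < r1 else -1
    sc = 1 if c0 < c1 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        pixels.append((r, c))
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return pixels


def _disc_offsets(radius):
    r = int(radius)
    ii, jj = np.mgrid[-r : r + 1, -r : r + 1]
    keep = ii * ii + jj * jj <= r * r
    return ii[keep], jj[keep]


def stroke_pixels(stroke, height, width):
    """Rasterise one stroke: Bresenham polyline dilated by a disc.

    Returns a boolean (height, width) grid.
    """
    mask = np.zeros((height, width), dtype=bool)
    pts = stroke.points
    line = []
    if len(pts) == 1:
        line = [pts[0]]
    else:
        for a, b in zip(pts[:-1], pts[1:]):
            line.extend(bresenham_line(a, b))
    rr = np.array([p[0] for p in line])
    cc = np.array([p[1] for p in line])
    if stroke.radius == 0:
        mask[rr, cc] = True
        return mask
    di, dj = _disc_offsets(stroke.radius)
    rr = (rr[:, None] + di[None, :]).ravel()
    cc = (cc[:, None] + dj[None, :]).ravel()
    keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
    mask[rr[keep], cc[keep]] = True
    return mask


def rasterize_scribbles(scribbles: ScribbleSet) -> np.ndarray:
    """Render a scribble set as a marker grid.

    Each stroke is drawn as its dilated Bresenham polyline; later strokes
    overwrite earlier ones where they overlap (the app lets users redraw,
    so the most recent input wins).  Untouched pixels stay 0.

    Returns
    -------
    ndarray of int, shape (image_height, image_width)
        0 = unlabelled, 1 = background, 2 = foot, 3 = ulcer.
    """
    h, w = scribbles.image_height, scribbles.image_width
    markers = np.zeros((h, w), dtype=np.int32)
    for i, stroke in enumerate(scribbles.strokes):
        for r, c in stroke.points:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"stroke {i}: point ({r}, {c}) out of bounds")
        markers[stroke_pixels(stroke, h, w)] = MARKER_CODES[stroke.label]
    return markers


def validate_scribbles(scribbles, stage, foot_mask=None):
    """Check a scribble set before running the given segmentation stage.

    stage ``foot`` needs at least one background and one foot stroke;
    stage ``ulcer`` needs at least one ulcer stroke and, given the foot
    mask from stage one, flags ulcer strokes whose pixels leave the foot
    (the stroke "crosses the foot edge" — a classic cause of bad results).

    Returns a list of :class:`Issue`; an empty list means the set is usable.
    """
    if stage not in ("foot", "ulcer"):
        raise ValueError(f"unknown stage {stage!r}")
    issues = []
    if stage == "foot":
        for label in ("background", "foot"):
            if not scribbles.with_label(label):
                issues.append(
                    Issue("missing_label", None, f"no {label} stroke present")
                )
        return issues

    if foot_mask is None:
        raise ValueError("stage='ulcer' requires the stage-one foot_mask")
    ulcer_strokes = scribbles.with_label("ulcer")
    if not ulcer_strokes:
        issues.append(Issue("missing_label", None, "no ulcer stroke present"))
        return issues
    foot_mask = np.asarray(foot_mask, dtype=bool)
    for i, stroke in enumerate(scribbles.strokes):
        if stroke.label != "ulcer":
            continue
        px = stroke_pixels(stroke, scribbles.image_height, scribbles.image_width)
        n_out = int(np.count_nonzero(px & ~foot_mask))
        if n_out:
            issues.append(
                Issue(
                    "crosses_edge",
                    i,
                    f"ulcer stroke {i} crosses the foot edge "
                    f"({n_out} pixels outside the foot)",
                )
            )
    return issues
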