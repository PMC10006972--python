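"""Synthetic foot-photo scenes with exact ground truth.

Real foot-check photos are flash-lit feet on a dark background.  The
generator emulates that contract — a bright, smooth foot silhouette
(ellipse plus toe lobes) on a dark background, a darker red ulcer blob
inside the foot, radial flash falloff, Gaussian sensor noise — plus the
documented failure modes: skin of the leg entering the frame, bright
spots in the background, and scribbles that cut across the wound edge.

Everything is deterministic given the seed, and every scene carries
pixel-exact masks so the segmentation pipeline can be scored without
any real data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .engagement import EngagementEvent, EngagementLog
from .marking import DEFAULT_STROKE_RADIUS, ScribbleSet, Stroke, stroke_pixels

# colours chosen for the contrasts the watershed needs: skin vs background
# ~145 grey levels, ulcer vs skin ~100 (well above the 40-level floor)
SKIN_RGB = (205, 160, 130)
ULCER_RGB = (130, 40, 40)
BACKGROUND_RGB = (25, 22, 20)
LEG_RGB = (195, 152, 124)
BRIGHT_SPOT_RGB = (250, 250, 250)

FRACTION_TOL = 0.005

_SERIES_EPOCH = dt.datetime(2023, 1, 2, 9, 0, 0)


class SceneError(ValueError):
    """Raised when requested scene parameters are infeasible."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic foot photo.

    ``foot_scale`` is the fraction of the image height the foot
    occupies; ``ulcer_fraction_target`` the requested ulcer/foot pixel
    ratio; ``illumination_falloff`` the strength of the radial flash
    model (0 = perfectly even); ``noise_sd`` the per-channel Gaussian
    noise in 8-bit intensity units.
    """

    image_height: int = 256
    image_width: int = 256
    foot_scale: float = 0.7
    ulcer_fraction_target: float = 0.05
    illumination_falloff: float = 0.3
    noise_sd: float = 2.0
    distractors: frozenset = frozenset()
    ulcer_contrast: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image must be at least 64x64")
        if not (0.0 <= self.ulcer_fraction_target <= 0.5):
            raise ValueError("ulcer_fraction_target must lie in [0, 0.5]")
        if self.illumination_falloff < 0 or self.noise_sd < 0:
            raise ValueError("illumination_falloff and noise_sd must be >= 0")
        bad = set(self.distractors) - {"leg_skin", "bright_spot"}
        if bad:
            raise ValueError(f"unknown distractors: {sorted(bad)}")
        object.__setattr__(self, "distractors", frozenset(self.distractors))


@dataclass(frozen=True)
class GroundTruth:
    foot_mask: np.ndarray
    ulcer_mask: np.ndarray
    realized_ulcer_fraction: float
    seed: int
    distractor_masks: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrajectoryParams:
    """Exponential healing trajectory: the ulcer fraction at check k is
    baseline x rate^(k * interval_days / 7), with optional multiplicative
    log-normal measurement noise and occasional edge-crossing scribbles
    that produce analysis outliers."""

    baseline_fraction: float = 0.08
    weekly_shrink_rate: float = 0.8
    n_checks: int = 5
    interval_days: int = 7
    measurement_noise_sd: float = 0.0
    outlier_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_checks < 1:
            raise ValueError("n_checks must be >= 1")
        if self.interval_days < 1:
            raise ValueError("interval_days must be >= 1")
        if not (0.0 <= self.weekly_shrink_rate <= 1.0):
            raise ValueError("weekly_shrink_rate must lie in [0, 1]")


@dataclass(frozen=True)
class EngagementArchetype:
    kind: str = "continuous"
    study_days: int = 84
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("continuous", "temporary", "failed"):
            raise ValueError(f"unknown engagement kind {self.kind!r}")
        if self.study_days < 28:
            raise ValueError("study_days must be >= 28")


@dataclass(frozen=True)
class HealingCheck:
    """One entry of a synthetic healing series."""

    date: dt.datetime
    image: np.ndarray
    truth: GroundTruth
    scribbles: ScribbleSet
    scribble_quality: str


def _foot_mask(params: SceneParams) -> np.ndarray:
    """Foot silhouette: vertical ellipse with five toe lobes at the top."""
    h, w = params.image_height, params.image_width
    cy, cx = h / 2.0, w / 2.0
    a = params.foot_scale * h / 2.0  # vertical semi-axis
    b = 0.42 * a
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    mask = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    # toe lobes along the upper arc
    toe_r = 0.10 * a
    top = cy - a
    for k in range(5):
        t = (k - 2) / 2.6  # spread across the forefoot
        tx = cx + t * b * 0.95
        ty = top + toe_r * 0.6 + 0.18 * a * t * t
        mask |= (yy - ty) ** 2 + (xx - tx) ** 2 <= toe_r**2
    return mask


def _disc(h, w, cy, cx, radius):
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def generate_scene(params: SceneParams):
    """Render one scene; returns (image, truth).

    The ulcer blob radius is adjusted by bisection until the realised
    pixel fraction is within +/-0.005 of the target.  Identical params
    (including seed) give byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    foot = _foot_mask(params)
    foot_px = int(foot.sum())

    # ulcer centre: jittered below the foot centre, well inside
    interior = ndi.binary_erosion(foot, iterations=4)
    cy = h / 2.0 + rng.uniform(0.02, 0.12) * h * params.foot_scale / 2
    cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w

    ulcer = np.zeros_like(foot)
    target = params.ulcer_fraction_target
    if target > 0:
        want = target * foot_px

        def frac(radius):
            return int((_disc(h, w, cy, cx, radius) & interior).sum()) / foot_px

        lo, hi = 0.0, max(h, w) / 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if frac(mid) < target:
                lo = mid
            else:
                hi = mid
        ulcer = _disc(h, w, cy, cx, hi) & interior
        realized = ulcer.sum() / foot_px
        if abs(realized - target) > FRACTION_TOL:
            raise SceneError(
                f"ulcer_fraction_target={target} infeasible for this foot "
                f"(closest realisable fraction {realized:.4f})"
            )

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = BACKGROUND_RGB
    distractor_masks = {}

    leg = np.zeros((h, w), dtype=bool)
    if "leg_skin" in params.distractors:
        # skin of the leg (band down to the foot) and arm (along the top)
        band_w = int(0.30 * w)
        c0 = w // 2 - band_w // 2
        top_of_foot = int(np.nonzero(foot.any(axis=1))[0][0])
        leg[: top_of_foot + 3, c0 : c0 + band_w] = True
        leg[: max(int(0.10 * h), 8), :] = True
        image[leg] = LEG_RGB
        distractor_masks["leg_skin"] = leg & ~foot

    image[foot] = SKIN_RGB
    # one-pixel soft transition outside the silhouette (optical blur);
    # gives the gradient a clean single-pixel ridge at the boundary
    dist_out = ndi.distance_transform_edt(~foot)
    foot_ring = (dist_out > 0) & (dist_out <= 1.0) & ~leg
    bg = np.array(BACKGROUND_RGB, dtype=np.float64)
    image[foot_ring] = 0.25 * np.array(SKIN_RGB, float) + 0.75 * bg
    ulcer_rgb = np.array(ULCER_RGB, dtype=np.float64)
    # scale ulcer darkness so luminance contrast vs skin ~= ulcer_contrast
    skin_lum = 0.299 * SKIN_RGB[0] + 0.587 * SKIN_RGB[1] + 0.114 * SKIN_RGB[2]
    base_lum = 0.299 * ulcer_rgb[0] + 0.587 * ulcer_rgb[1] + 0.114 * ulcer_rgb[2]
    want_lum = skin_lum - params.ulcer_contrast
    if base_lum > 0:
        ulcer_rgb = np.clip(ulcer_rgb * want_lum / base_lum, 0, 255)
    image[ulcer] = ulcer_rgb
    if ulcer.any():
        ulcer_ring = ndi.binary_dilation(ulcer) & ~ulcer
        image[ulcer_ring] = 0.25 * ulcer_rgb + 0.75 * np.array(SKIN_RGB, float)

    if "bright_spot" in params.distractors:
        sy, sx = 0.88 * h, 0.10 * w
        spot = _disc(h, w, sy, sx, 0.06 * min(h, w)) & (dist_out > 3)
        image[spot] = BRIGHT_SPOT_RGB
        distractor_masks["bright_spot"] = spot

    if params.illumination_falloff > 0:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        d2 = ((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / ((h / 2) ** 2 + (w / 2) ** 2)
        image *= 1.0 / (1.0 + params.illumination_falloff * d2)[..., None]

    if params.noise_sd > 0:
        image += rng.normal(0.0, params.noise_sd, size=image.shape)

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        foot_mask=foot,
        ulcer_mask=ulcer,
        realized_ulcer_fraction=float(ulcer.sum() / foot_px),
        seed=params.seed,
        distractor_masks=distractor_masks,
    )
    return image, truth


def _longest_run(row_mask):
    """(start, end) column indices of the longest True run, or None."""
    idx = np.flatnonzero(row_mask)
    if idx.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    k = int(np.argmax(ends - starts))
    return int(idx[starts[k]]), int(idx[ends[k]])


def _contour_loop(mask, margin, step=6):
    """Closed polyline hugging ``mask`` at roughly ``margin`` pixels
    (Euclidean distance, so diagonal clearance holds too)."""
    dil = ndi.distance_transform_edt(~mask) <= margin
    contours = measure.find_contours(dil.astype(float), 0.5)
    contour = max(contours, key=len)
    pts = contour[::step]
    h, w = mask.shape
    pts = [(int(round(r)), int(round(c))) for r, c in pts]
    pts = [(min(max(r, 0), h - 1), min(max(c, 0), w - 1)) for r, c in pts]
    if pts[0] != pts[-1]:
        pts.append(pts[0])
    # drop consecutive duplicates
    out = [pts[0]]
    for p in pts[1:]:
        if p != out[-1]:
            out.append(p)
    return out


def generate_scribbles(
    truth: GroundTruth,
    quality: str = "good",
    radius: int = DEFAULT_STROKE_RADIUS,
) -> ScribbleSet:
    """Emulate a user's scribble set over a known scene.

    ``good`` follows the instructions (loop around the foot, strokes on
    clean skin, a mark inside the wound); ``edge_crossing`` drags the
    ulcer stroke across the wound edge; ``missing_background`` forgets
    the loop around the foot.
    """
    if quality not in ("good", "edge_crossing", "missing_background"):
        raise ValueError(f"unknown scribble quality {quality!r}")
    foot = np.asarray(truth.foot_mask, dtype=bool)
    ulcer = np.asarray(truth.ulcer_mask, dtype=bool)
    h, w = foot.shape
    strokes = []

    # background loop outside the foot, >= 3 px clearance after dilation
    if quality != "missing_background":
        loop = _contour_loop(foot, margin=radius + 4)
        strokes.append(Stroke("background", tuple(loop), radius=radius))

    # foot strokes on clean skin, clear of the ulcer
    ok = ndi.binary_erosion(foot, iterations=radius + 2)
    if ulcer.any():
        ok &= ~ndi.binary_dilation(ulcer, iterations=radius + 3)
    rows = np.flatnonzero(ok.any(axis=1))
    if rows.size == 0:
        raise SceneError("no clean skin available for a foot stroke")
    for q in (0.30, 0.70):
        row = int(rows[int(q * (rows.size - 1))])
        run = _longest_run(ok[row])
        if run is None:
            continue
        c0, c1 = run
        if c1 - c0 >= 2:
            strokes.append(
                Stroke("foot", ((row, c0 + 1), (row, c1 - 1)), radius=radius)
            )
    if not any(s.label == "foot" for s in strokes):
        raise SceneError("could not place a foot stroke")

    # ulcer stroke
    if quality == "edge_crossing":
        if not ulcer.any():
            raise SceneError("edge_crossing scribbles need a non-empty ulcer")
        rs, cs = np.nonzero(ulcer)
        cy, cx = float(rs.mean()), float(cs.mean())
        reach = int(cs.max() - cx) + radius + 5
        end_c = min(int(cx) + reach, w - 1)
        strokes.append(
            Stroke("ulcer", ((int(cy), int(cx)), (int(cy), end_c)), radius=radius)
        )
    else:
        if not ulcer.any():
            raise SceneError("good scribbles need a non-empty ulcer mask")
        dist = ndi.distance_transform_edt(ulcer)
        r, c = np.unravel_index(int(np.argmax(dist)), dist.shape)
        r_use = min(radius, max(int(dist[r, c]) - 2, 0))
        # short horizontal dash if it fits, else a tap
        half = max(int(dist[r, c]) - r_use - 2, 0)
        pts = ((int(r), int(c) - half), (int(r), int(c) + half)) if half else ((int(r), int(c)),)
        strokes.append(Stroke("ulcer", pts, radius=r_use))

    return ScribbleSet(tuple(strokes), image_height=h, image_width=w)


def generate_healing_series(
    scene_params: SceneParams, traj: TrajectoryParams
) -> list:
    """Weekly (or ``interval_days``) checks of an exponentially healing ulcer.

    Returns a list of :class:`HealingCheck`, dates strictly increasing.
    Checks drawn as outliers carry edge-crossing scribbles, which the
    downstream analysis should flag rather than trust.
    """
    rng = np.random.default_rng(traj.seed)
    out = []
    for k in range(traj.n_checks):
        days = k * traj.interval_days
        frac = traj.baseline_fraction * traj.weekly_shrink_rate ** (days / 7.0)
        if traj.measurement_noise_sd > 0:
            frac *= float(np.exp(rng.normal(0.0, traj.measurement_noise_sd)))
        frac = float(min(max(frac, 0.0), 0.5))
        quality = "good"
        if traj.outlier_probability > 0 and rng.random() < traj.outlier_probability:
            quality = "edge_crossing"
        check_seed = int(rng.integers(0, 2**31 - 1))
        params = SceneParams(
            image_height=scene_params.image_height,
            image_width=scene_params.image_width,
            foot_scale=scene_params.foot_scale,
            ulcer_fraction_target=frac,
            illumination_falloff=scene_params.illumination_falloff,
            noise_sd=scene_params.noise_sd,
            distractors=scene_params.distractors,
            ulcer_contrast=scene_params.ulcer_contrast,
            seed=check_seed,
        )
        image, truth = generate_scene(params)
        scribbles = generate_scribbles(truth, quality=quality)
        out.append(
            HealingCheck(
                date=_SERIES_EPOCH + dt.timedelta(days=days),
                image=image,
                truth=truth,
                scribbles=scribbles,
                scribble_quality=quality,
            )
        )
    return out


def generate_engagement_log(arch: EngagementArchetype) -> EngagementLog:
    """Synthesize a foot-check log matching one of the three observed
    usage patterns: continuous (20-45 checks spread over the study),
    temporary (10-19 checks with a multi-week gap), failed (1-9 checks,
    all in the first three weeks)."""
    rng = np.random.default_rng(arch.seed)
    start = _SERIES_EPOCH
    days = arch.study_days
    if arch.kind == "continuous":
        total = int(rng.integers(20, 46))
        offsets = np.sort(rng.uniform(0, days, size=total))
    elif arch.kind == "temporary":
        total = int(rng.integers(10, 20))
        gap_start = float(rng.uniform(0.25, 0.45)) * days
        gap_len = float(rng.uniform(21, 35))
        n_early = max(int(round(total * 0.6)), 1)
        early = rng.uniform(0, gap_start, size=n_early)
        late = rng.uniform(
            min(gap_start + gap_len, days - 1), days, size=total - n_early
        )
        offsets = np.sort(np.concatenate([early, late]))
    else:  # failed
        total = int(rng.integers(1, 10))
        offsets = np.sort(rng.uniform(0, 21, size=total))
    events = tuple(
        EngagementEvent(
            timestamp=start + dt.timedelta(days=float(d)),
            kind="foot_check",
            relative_size_pct=float(np.round(100 * rng.uniform(0.2, 1.2), 1)),
        )
        for d in offsets
    )
    return EngagementLog(events=events, study_start=start)
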