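"""Seedable generator of fundus-like scenes with exact ground truth.

The generator does not aim at photo-realism.  It reproduces the handful of
image properties that rule-based optic-disc (OD) localization exploits and
the artifact modes it must survive:

* a bright circular retina on a dark background;
* a locally-brightest elliptical OD containing an even brighter cup, whose
  diameter ratio to the disc (the cup-to-disc ratio, CDR) is the structural
  glaucoma proxy used for class labels;
* dark curvilinear vessels converging on the OD;
* optionally a bright fringe arc at the retinal rim (ambient-light leakage)
  and bright cloud-like reflection spots;
* inter-image variation in illumination, contrast and resolution.

Every output is a pure function of a :class:`SyntheticSpec` (which includes
its own seed): the same spec renders a bit-identical image.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .types import BoundingBox, CircleProposal, FundusImage, ValidationError

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_image",
    "generate_dataset",
    "add_fringe",
    "add_reflections",
    "default_ranges",
    "standard_suite",
    "MANIFEST_COLUMNS",
]

#: red-dominant channel mix; OD/cup stay brightest in every channel
_CHANNEL_MIX = (1.0, 0.62, 0.30)

MANIFEST_COLUMNS = [
    "image_id", "path", "x_min", "y_min", "x_max", "y_max",
    "cx", "cy", "r", "label", "cdr", "seed",
]


@dataclass
class SyntheticSpec:
    """Full parametric description of one generated fundus scene.

    Intensities are 8-bit levels of the noise-free grayscale scene and must
    satisfy ``background_level < retina_level < od_brightness <=
    cup_brightness``.  Geometry is relative: the retina radius is a fraction
    of the half-width, the OD center is polar within the retina, the OD and
    cup radii are fractions of their parent structure.
    """

    image_size: int = 1500
    retina_radius_frac: float = 0.92
    retina_center_jitter: float = 0.0
    od_eccentricity: float = 0.50
    od_angle: float = 0.0
    od_radius_frac: float = 0.10
    cdr: float = 0.40
    od_brightness: float = 190.0
    cup_brightness: float = 235.0
    background_level: float = 8.0
    retina_level: float = 90.0
    n_vessels: int = 6
    vessel_darkness: float = 45.0
    fringe: str = "none"  # {"none", "arc"}
    fringe_extent_deg: float = 90.0
    fringe_brightness: float = 250.0
    fringe_thickness_frac: float = 0.025
    reflections: int = 0
    reflection_sigma_frac: float = 0.03  # of retina radius, per-blob mean
    reflection_peak: float = 120.0
    noise_sigma: float = 0.0
    seed: int = 0

    # axis ratio of the OD ellipse is drawn in this band (never a perfect circle
    # shortcut, never far from round)
    _AXIS_RATIO_BAND = (0.9, 1.1)

    def validate(self) -> None:
        def fail(field: str, msg: str) -> None:
            raise ValidationError(f"SyntheticSpec.{field}: {msg}")

        if self.image_size < 64:
            fail("image_size", f"must be >= 64, got {self.image_size}")
        if not (0.7 < self.retina_radius_frac <= 1.0):
            fail("retina_radius_frac", f"must be in (0.7, 1.0], got {self.retina_radius_frac}")
        if not (0.05 <= self.od_radius_frac <= 0.15):
            fail("od_radius_frac", f"must be in [0.05, 0.15], got {self.od_radius_frac}")
        if not (0.2 <= self.cdr <= 0.95):
            fail("cdr", f"must be in [0.2, 0.95], got {self.cdr}")
        if not (0 <= self.od_eccentricity < 1):
            fail("od_eccentricity", f"must be in [0, 1), got {self.od_eccentricity}")
        ordered = (
            self.background_level < self.retina_level < self.od_brightness <= self.cup_brightness
        )
        if not ordered:
            fail(
                "background_level/retina_level/od_brightness/cup_brightness",
                "intensity ordering background < retina < od <= cup violated: "
                f"{self.background_level}, {self.retina_level}, "
                f"{self.od_brightness}, {self.cup_brightness}",
            )
        for name in ("background_level", "retina_level", "od_brightness", "cup_brightness"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                fail(name, f"must be in [0, 255], got {v}")
        if self.fringe not in ("none", "arc"):
            fail("fringe", f"must be 'none' or 'arc', got {self.fringe!r}")
        if self.reflections < 0:
            fail("reflections", "must be >= 0")
        if self.noise_sigma < 0:
            fail("noise_sigma", "must be >= 0")
        # OD (largest possible semi-axis) must fit entirely inside the retina
        max_axis = math.sqrt(max(self._AXIS_RATIO_BAND))
        if (self.od_eccentricity + self.od_radius_frac * max_axis) >= 1.0:
            fail(
                "od_eccentricity",
                "OD ellipse does not fit inside retina: "
                f"ecc {self.od_eccentricity} + max semi-axis "
                f"{self.od_radius_frac * max_axis:.3f} (fractions of retina radius) >= 1",
            )


@dataclass
class GroundTruth:
    """Exact OD location and class label of a generated scene."""

    od_box: BoundingBox
    od_circle: CircleProposal
    label: str  # {"healthy", "glaucoma"}
    cdr: float
    retina_circle: CircleProposal | None = None


def _elliptic_radius(shape, cx, cy, a, b, theta):
    """Normalized elliptical radius rho (1.0 on the ellipse boundary)."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    dx = xx - cx
    dy = yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


#: shape exponent of the disc brightness falloff between cup core and disc rim
_DISC_PROFILE_EXPONENT = 1.2

#: the specular bright core occupies this fraction of the cup radius
_CUP_CORE_FRAC = 0.6

#: height of the brightness dome at the very cup center
_CUP_DOME = 5.0


def _disc_profile(rho: np.ndarray, cdr: float, rim_level: float, cup_level: float):
    """Radial brightness of the OD: bright cup core, smooth falloff to the rim.

    Real discs are not flat plateaus: brightness peaks in a specular core
    inside the cup — smaller than the full anatomical cup — and decays
    smoothly across the pallor zone and neuroretinal rim toward the disc
    boundary.  That gradual falloff is what lets a top-percentile threshold
    recover a disc-scaled (not pinpoint) bright region.  The core radius is
    ``_CUP_CORE_FRAC * cdr`` in normalized elliptical radius ``rho`` (1.0 at
    the disc boundary), sitting at ``cup_level`` plus a small central dome;
    outside it brightness interpolates down to ``rim_level`` at the boundary.
    The core area therefore grows as cdr^2 — the class signal the disc
    classifier is meant to pick up.
    """
    core = _CUP_CORE_FRAC * cdr
    t = np.clip((1.0 - rho) / max(1.0 - core, 1e-6), 0.0, 1.0)
    out = rim_level + (cup_level - rim_level) * t**_DISC_PROFILE_EXPONENT
    dome = min(_CUP_DOME, 254.0 - cup_level)
    in_core = rho <= core
    out = np.where(
        in_core,
        cup_level + dome * (1.0 - (rho / max(core, 1e-6)) ** 2),
        out,
    )
    return out


def _stamp_disc(buf: np.ndarray, cy: float, cx: float, radius: float) -> None:
    """Set a filled disc of ``radius`` to True in ``buf`` (in place)."""
    r = max(radius, 0.5)
    y0, y1 = int(cy - r - 1), int(cy + r + 2)
    x0, x1 = int(cx - r - 1), int(cx + r + 2)
    y0, x0 = max(y0, 0), max(x0, 0)
    y1, x1 = min(y1, buf.shape[0]), min(x1, buf.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    buf[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _render_vessels(scene, rng, od_cx, od_cy, ret_cx, ret_cy, ret_r, n_vessels, darkness, size):
    """Darken the scene along quadratic Bezier strips radiating from the OD.

    Widths taper from 1-8 px (at a 1500 px working scale) near the disc down
    to ~1 px at the rim; curvature comes from a perpendicular offset of the
    Bezier control point.
    """
    if n_vessels <= 0 or darkness <= 0:
        return
    mask = np.zeros(scene.shape, dtype=bool)
    scale = size / 1500.0
    angles = rng.uniform(0, 2 * math.pi, size=n_vessels)
    for ang in angles:
        # endpoint near the rim, start at the disc center (small jitter)
        end_r = ret_r * rng.uniform(0.85, 0.98)
        p0 = np.array([od_cx + rng.normal(0, 2 * scale), od_cy + rng.normal(0, 2 * scale)])
        p2 = np.array([ret_cx + end_r * math.cos(ang), ret_cy + end_r * math.sin(ang)])
        mid = (p0 + p2) / 2
        chord = p2 - p0
        norm = np.array([-chord[1], chord[0]])
        nlen = np.hypot(*norm)
        if nlen < 1e-9:
            continue
        p1 = mid + norm / nlen * rng.uniform(-0.25, 0.25) * np.hypot(*chord)
        w0 = rng.uniform(2.0, 8.0) * scale  # width at origin
        n_steps = max(32, int(np.hypot(*chord) / max(1.0, scale)))
        t = np.linspace(0.0, 1.0, n_steps)
        pts = ((1 - t) ** 2)[:, None] * p0 + (2 * t * (1 - t))[:, None] * p1 + (t**2)[:, None] * p2
        widths = np.maximum(1.0 * scale, w0 * (1 - 0.85 * t))
        for (x, y), w in zip(pts, widths):
            _stamp_disc(mask, y, x, w / 2.0)
    scene[mask] -= darkness


def _od_geometry(spec: SyntheticSpec, rng: np.random.Generator, ret_cx, ret_cy, ret_r):
    """Draw the OD ellipse parameters; returns (cx, cy, a, b, theta, od_r)."""
    od_r = spec.od_radius_frac * ret_r
    ecc = spec.od_eccentricity * ret_r
    cx = ret_cx + ecc * math.cos(spec.od_angle)
    cy = ret_cy + ecc * math.sin(spec.od_angle)
    q = rng.uniform(*spec._AXIS_RATIO_BAND)
    a = od_r * math.sqrt(q)
    b = od_r / math.sqrt(q)
    theta = rng.uniform(0, math.pi)
    return cx, cy, a, b, theta, od_r


def _ellipse_tight_box(cx, cy, a, b, theta, size) -> BoundingBox:
    ex = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    ey = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    return BoundingBox(
        int(math.floor(cx - ex)), int(math.floor(cy - ey)),
        int(math.ceil(cx + ex)), int(math.ceil(cy + ey)),
    ).clipped(size, size)


def generate_image(
    spec: SyntheticSpec, label_threshold: float = 0.65
) -> tuple[FundusImage, GroundTruth]:
    """Render one fundus scene and its exact ground truth.

    The scene is composed in grayscale (background, retina disc, OD ellipse,
    cup ellipse, vessels), blurred slightly so structure edges are not
    single-pixel steps, mapped to a red-dominant RGB mix, then fringe /
    reflection artifacts and additive Gaussian noise are applied per the
    spec.  ``label = "glaucoma"`` iff ``cdr > label_threshold``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size

    # retina geometry
    half = n / 2.0
    ret_r = spec.retina_radius_frac * half
    if spec.retina_center_jitter > 0:
        jang = rng.uniform(0, 2 * math.pi)
        jmag = rng.uniform(0, spec.retina_center_jitter)
    else:
        jang, jmag = 0.0, 0.0
    ret_cx = half + jmag * math.cos(jang)
    ret_cy = half + jmag * math.sin(jang)

    od_cx, od_cy, a, b, theta, od_r = _od_geometry(spec, rng, ret_cx, ret_cy, ret_r)

    scene = np.full((n, n), spec.background_level, dtype=np.float64)
    yy, xx = np.ogrid[:n, :n]
    retina_mask = (xx - ret_cx) ** 2 + (yy - ret_cy) ** 2 <= ret_r**2
    scene[retina_mask] = spec.retina_level
    rho = _elliptic_radius((n, n), od_cx, od_cy, a, b, theta)
    od_mask = rho <= 1.0
    scene[od_mask] = _disc_profile(
        rho, spec.cdr, spec.od_brightness, spec.cup_brightness
    )[od_mask]

    _render_vessels(
        scene, rng, od_cx, od_cy, ret_cx, ret_cy, ret_r,
        spec.n_vessels, spec.vessel_darkness, n,
    )
    scene = ndimage.gaussian_filter(scene, sigma=max(1.0, n / 1000.0))
    # the blur must not leak disc brightness outside the retina nor lift the
    # global maximum outside the cup; re-impose the background
    scene[~retina_mask] = spec.background_level
    np.clip(scene, 0, 255, out=scene)

    rgb = np.empty((n, n, 3), dtype=np.float64)
    for c, m in enumerate(_CHANNEL_MIX):
        rgb[..., c] = scene * m

    image = FundusImage(
        pixels=np.clip(np.rint(rgb), 0, 255).astype(np.uint8),
        image_id=f"synthetic-{spec.seed}",
    )

    retina_circle = CircleProposal(ret_cx, ret_cy, ret_r)
    od_box = _ellipse_tight_box(od_cx, od_cy, a, b, theta, n)
    gt = GroundTruth(
        od_box=od_box,
        od_circle=CircleProposal(od_cx, od_cy, od_r),
        label="glaucoma" if spec.cdr > label_threshold else "healthy",
        cdr=spec.cdr,
        retina_circle=retina_circle,
    )

    if spec.fringe == "arc":
        image = add_fringe(
            image, retina_circle,
            extent=spec.fringe_extent_deg,
            brightness=spec.fringe_brightness,
            seed=spec.seed,
            thickness_frac=spec.fringe_thickness_frac,
        )
    if spec.reflections > 0:
        image = add_reflections(
            image, retina_circle, spec.reflections, seed=spec.seed,
            avoid_circle=gt.od_circle,
            sigma=spec.reflection_sigma_frac * ret_r,
            peak=spec.reflection_peak,
        )
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng((spec.seed, 0xA015E))
        noisy = image.pixels.astype(np.float64) + noise_rng.normal(
            0, spec.noise_sigma, size=image.pixels.shape
        )
        image = FundusImage(
            np.clip(np.rint(noisy), 0, 255).astype(np.uint8), image.image_id
        )
    return image, gt


def add_fringe(
    image: FundusImage,
    retina_circle: CircleProposal,
    extent: float,
    brightness: float,
    seed: int = 0,
    thickness_frac: float = 0.025,
) -> FundusImage:
    """Brighten a thin annulus arc at the retinal rim (ambient-light fringe).

    Only pixels inside the annulus ``[(1 - thickness_frac) r, r]`` and within
    the arc of ``extent`` degrees (start angle drawn from ``seed``) change;
    each affected pixel is raised 90% of the way toward ``brightness`` (never
    lowered).
    """
    if extent <= 0:
        raise ValidationError(f"fringe extent must be > 0 degrees, got {extent}")
    rng = np.random.default_rng((seed, 0xF21), )
    start = rng.uniform(0, 2 * math.pi)
    h, w = image.height, image.width
    yy, xx = np.ogrid[:h, :w]
    dx = xx - retina_circle.cx
    dy = yy - retina_circle.cy
    rr = np.hypot(dx, dy)
    r_out = retina_circle.r
    r_in = r_out * (1.0 - thickness_frac)
    in_annulus = (rr >= r_in) & (rr <= r_out)
    ang = np.mod(np.arctan2(dy, dx) - start, 2 * math.pi)
    in_arc = ang <= math.radians(min(extent, 360.0))
    region = in_annulus & in_arc
    px = image.pixels.astype(np.float64)
    target = np.maximum(px[region], brightness * np.array(_CHANNEL_MIX))
    px[region] = px[region] + 0.9 * (target - px[region])
    return FundusImage(
        np.clip(np.rint(px), 0, 255).astype(np.uint8), image.image_id
    )


def add_reflections(
    image: FundusImage,
    retina_circle: CircleProposal,
    count: int,
    seed: int = 0,
    avoid_circle: CircleProposal | None = None,
    sigma: float | None = None,
    peak: float = 120.0,
) -> FundusImage:
    """Add bright Gaussian "cloud" spots inside the retina, away from the OD.

    Blob centers are rejection-sampled so their distance to ``avoid_circle``'s
    center exceeds ``avoid_circle.r + 3 sigma_blob``; per-blob sigma and peak
    vary around the given values.  ``count = 0`` returns the image unchanged.
    """
    if count < 0:
        raise ValidationError(f"reflection count must be >= 0, got {count}")
    if count == 0:
        return image
    rng = np.random.default_rng((seed, 0x5071))
    if sigma is None:
        sigma = 0.03 * retina_circle.r
    px = image.pixels.astype(np.float64)
    h, w = image.height, image.width
    placed = 0
    attempts = 0
    while placed < count and attempts < 1000 * count:
        attempts += 1
        s = sigma * rng.uniform(0.6, 1.4)
        p = peak * rng.uniform(0.6, 1.2)
        rad = retina_circle.r * math.sqrt(rng.uniform(0, 0.7))
        ang = rng.uniform(0, 2 * math.pi)
        bx = retina_circle.cx + rad * math.cos(ang)
        by = retina_circle.cy + rad * math.sin(ang)
        if avoid_circle is not None:
            d = math.hypot(bx - avoid_circle.cx, by - avoid_circle.cy)
            if d <= avoid_circle.r + 3 * s:
                continue
        y0, y1 = max(0, int(by - 4 * s)), min(h, int(by + 4 * s) + 1)
        x0, x1 = max(0, int(bx - 4 * s)), min(w, int(bx + 4 * s) + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        bump = p * np.exp(-(((xx - bx) ** 2 + (yy - by) ** 2) / (2 * s * s)))
        for c, m in enumerate(_CHANNEL_MIX):
            px[y0:y1, x0:x1, c] += bump * m
        placed += 1
    if placed < count:
        raise ValidationError(
            f"could not place {count} reflections away from the OD "
            f"(placed {placed})"
        )
    return FundusImage(
        np.clip(np.rint(px), 0, 255).astype(np.uint8), image.image_id
    )


def default_ranges() -> dict:
    """Per-image parameter ranges a screening-scale fundus archive shows.

    ``(lo, hi)`` tuples are sampled uniformly; lists are sampled by choice.
    CDR is sampled conditionally on the class label (healthy below the
    labelling threshold, glaucomatous above it) so dataset class fractions
    are exact.
    """
    return {
        "image_size": [900, 1200, 1500],
        "retina_radius_frac": (0.82, 0.96),
        "retina_center_jitter_frac": (0.0, 0.02),  # of image size
        "od_eccentricity": (0.30, 0.60),
        "od_angle": (0.0, 2 * math.pi),
        "od_radius_frac": (0.10, 0.15),
        "cdr_healthy": (0.25, 0.55),
        "cdr_glaucoma": (0.70, 0.92),
        "background_level": (4.0, 16.0),
        "retina_level": (70.0, 110.0),
        "od_brightness": (170.0, 205.0),
        "cup_brightness": (215.0, 245.0),
        "n_vessels": (4, 9),
        "vessel_darkness": (35.0, 60.0),
        "noise_sigma": (0.0, 3.0),
    }


def _draw(rng, rng_spec):
    if isinstance(rng_spec, (list, tuple)) and isinstance(rng_spec, list):
        return rng_spec[rng.integers(0, len(rng_spec))]
    lo, hi = rng_spec
    if isinstance(lo, int) and isinstance(hi, int):
        return int(rng.integers(lo, hi + 1))
    return float(rng.uniform(lo, hi))


def generate_dataset(
    n: int,
    ranges: dict | None = None,
    glaucoma_fraction: float = 0.25,
    seed: int = 0,
    label_threshold: float = 0.65,
    out_dir: str | Path | None = None,
    fringe_fraction: float = 0.0,
    reflection_fraction: float = 0.0,
):
    """Generate ``n`` scenes with exactly ``round(n * glaucoma_fraction)``
    glaucoma labels.

    Returns ``(items, manifest)`` where ``items`` is a list of
    ``(FundusImage, GroundTruth)`` and ``manifest`` a DataFrame with one row
    per image (box, circle, label, CDR, per-image seed).  With ``out_dir``
    set, images are written as PNG, the manifest as ``manifest.csv`` and the
    full specs as ``specs.json``.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not (0.0 <= glaucoma_fraction <= 1.0):
        raise ValidationError(f"glaucoma_fraction must be in [0, 1], got {glaucoma_fraction}")
    r = dict(default_ranges())
    if ranges:
        r.update(ranges)
    for key, val in r.items():
        if isinstance(val, (list, tuple)) and len(val) == 0:
            raise ValidationError(f"empty range for {key!r}")

    rng = np.random.default_rng(seed)
    n_glaucoma = int(round(n * glaucoma_fraction))
    labels = np.array(["glaucoma"] * n_glaucoma + ["healthy"] * (n - n_glaucoma))
    rng.shuffle(labels)

    items: list[tuple[FundusImage, GroundTruth]] = []
    specs: list[SyntheticSpec] = []
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for i in range(n):
        label = labels[i]
        size = _draw(rng, r["image_size"])
        cdr_range = r["cdr_glaucoma"] if label == "glaucoma" else r["cdr_healthy"]
        od_b = _draw(rng, r["od_brightness"])
        cup_b = max(od_b + 5.0, _draw(rng, r["cup_brightness"]))
        spec = SyntheticSpec(
            image_size=size,
            retina_radius_frac=_draw(rng, r["retina_radius_frac"]),
            retina_center_jitter=_draw(rng, r["retina_center_jitter_frac"]) * size,
            od_eccentricity=_draw(rng, r["od_eccentricity"]),
            od_angle=_draw(rng, r["od_angle"]),
            od_radius_frac=_draw(rng, r["od_radius_frac"]),
            cdr=_draw(rng, cdr_range),
            od_brightness=od_b,
            cup_brightness=cup_b,
            background_level=_draw(rng, r["background_level"]),
            retina_level=_draw(rng, r["retina_level"]),
            n_vessels=_draw(rng, r["n_vessels"]),
            vessel_darkness=_draw(rng, r["vessel_darkness"]),
            noise_sigma=_draw(rng, r["noise_sigma"]),
            fringe="arc" if rng.uniform() < fringe_fraction else "none",
            reflections=int(rng.integers(1, 4)) if rng.uniform() < reflection_fraction else 0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, gt = generate_image(spec, label_threshold=label_threshold)
        image.image_id = f"syn-{i:05d}"
        # by construction of the conditional CDR ranges the drawn label matches
        assert gt.label == label, "CDR range inconsistent with labelling threshold"
        path = ""
        if out_path is not None:
            path = str(out_path / f"{image.image_id}.png")
            Image.fromarray(image.pixels).save(path)
        items.append((image, gt))
        specs.append(spec)
        rows.append({
            "image_id": image.image_id,
            "path": path,
            "x_min": gt.od_box.x_min, "y_min": gt.od_box.y_min,
            "x_max": gt.od_box.x_max, "y_max": gt.od_box.y_max,
            "cx": gt.od_circle.cx, "cy": gt.od_circle.cy, "r": gt.od_circle.r,
            "label": gt.label, "cdr": gt.cdr, "seed": spec.seed,
        })

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        with open(out_path / "specs.json", "w") as fh:
            json.dump([dataclasses.asdict(s) for s in specs], fh, indent=1)
    return items, manifest


def standard_suite(n: int = 200, seed: int = 0):
    """The fixed clean localization test suite: no fringe, no reflections.

    Resolution, illumination, OD geometry and CDR still vary per image; this
    is the benchmark the localizer's quality floor is measured on.
    """
    return generate_dataset(
        n=n,
        glaucoma_fraction=0.25,
        seed=seed,
        fringe_fraction=0.0,
        reflection_fraction=0.0,
    )
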