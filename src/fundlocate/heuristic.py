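"""Rule-based optic-disc localization.

The algorithm exploits the fact that the OD is usually the brightest compact
region of a fundus photograph, after discounting two common artifacts: a
bright fringe at the retinal rim (ambient light leaking past the eye cup)
and shiny reflection spots.  The pipeline, run at a fixed working scale so a
single parameter set covers images of any resolution:

1. rescale the image to ``working_size`` (default 1500 px square);
2. estimate the retina as the Otsu-threshold foreground: its centroid and
   the equivalent-area radius ``sqrt(area / pi)``;
3. crop with a circular mask slightly smaller than the retina, discarding
   the rim and any fringe on it;
4. binarize adaptively at the mean intensity of the brightest 1% of nonzero
   pixels, keeping only OD-core-like regions;
5. erode (removing small reflective specks) then dilate (reconnecting the
   disc core split by vessels) with disc structuring elements;
6. take the largest connected component; its centroid and equivalent-area
   radius, inflated by ``proposal_scale``, form the circle proposal;
7. map the circle back to the original resolution and report its tight
   square bounding box.

If step 6 finds nothing the localizer falls back to the centroid of the
brightest 1% of pixels and flags the result low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology, transform
from skimage.filters import threshold_otsu

from .types import BoundingBox, CircleProposal, FundusImage, ValidationError

__all__ = [
    "HeuristicConfig",
    "LocalizationResult",
    "NoRetinaError",
    "NoDiscCandidateError",
    "estimate_retina",
    "crop_rim",
    "adaptive_binarize",
    "clean_mask",
    "propose_od",
    "localize",
]


class NoRetinaError(ValueError):
    """Otsu foreground too small: no retina found."""


class NoDiscCandidateError(ValueError):
    """Cleaned binary mask is empty: no disc candidate."""


@dataclass
class HeuristicConfig:
    """Tunable parameters of the rule-based localizer.

    All pixel quantities are at the ``working_size`` scale.  The brightest
    fraction used by the adaptive threshold is fixed at 1%; the erosion /
    dilation radii and the crop margin are the empirical knobs.
    ``max_disc_radius_frac`` is an optional sanity bound on the proposed
    radius (as a fraction of the retina radius); ``None`` disables it.
    """

    working_size: int = 1500
    crop_margin_frac: float = 0.95
    top_bright_frac: float = 0.01
    erode_radius: int = 2
    dilate_radius: int = 10
    proposal_scale: float = 1.5
    min_blob_area: int = 25
    max_disc_radius_frac: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.crop_margin_frac < 1):
            raise ValidationError(f"crop_margin_frac must be in (0,1), got {self.crop_margin_frac}")
        if not self.proposal_scale > 1:
            raise ValidationError(f"proposal_scale must be > 1, got {self.proposal_scale}")
        if not (0 < self.top_bright_frac < 1):
            raise ValidationError(f"top_bright_frac must be in (0,1), got {self.top_bright_frac}")
        if self.erode_radius < 0 or self.dilate_radius < 0:
            raise ValidationError("morphology radii must be >= 0")


@dataclass
class LocalizationResult:
    """Circle proposal + bounding box in original image coordinates."""

    circle: CircleProposal
    box: BoundingBox
    confidence: str = "normal"  # {"normal", "low"}
    image_id: str = ""


def _estimate_retina_gray(gray: np.ndarray) -> CircleProposal:
    lo, hi = float(gray.min()), float(gray.max())
    if hi - lo < 1e-9:
        # constant image: Otsu undefined; whole frame is foreground if bright
        fg = np.ones_like(gray, dtype=bool) if hi > 0 else np.zeros_like(gray, dtype=bool)
    else:
        t = threshold_otsu(gray)
        fg = gray > t
    area = int(np.count_nonzero(fg))
    if area < 0.01 * gray.size:
        raise NoRetinaError(
            f"no retina found: Otsu foreground covers {area} px "
            f"(< 1% of {gray.size})"
        )
    # centroid from column/row marginals (avoids materializing index arrays)
    col = fg.sum(axis=0)
    row = fg.sum(axis=1)
    cx = float((col * np.arange(fg.shape[1])).sum() / area)
    cy = float((row * np.arange(fg.shape[0])).sum() / area)
    return CircleProposal(cx=cx, cy=cy, r=float(np.sqrt(area / np.pi)))


def estimate_retina(image: FundusImage) -> CircleProposal:
    """Estimate the retina disc via Otsu foreground on grayscale luminance.

    Returns the foreground centroid and equivalent-area radius
    ``sqrt(area / pi)``.  Raises :class:`NoRetinaError` when the foreground
    covers less than 1% of the frame (e.g. an all-black image).
    """
    return _estimate_retina_gray(image.grayscale())


def _rim_keep_mask(shape, retina: CircleProposal, margin_frac: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - retina.cx) ** 2 + (yy - retina.cy) ** 2 <= (margin_frac * retina.r) ** 2


def crop_rim(image: FundusImage, retina: CircleProposal, margin_frac: float) -> FundusImage:
    """Zero every pixel outside the circle ``margin_frac * retina.r``.

    This discards the retinal rim — and with it any bright fringe thinner
    than ``(1 - margin_frac)`` of the retina radius.
    """
    if not (0 < margin_frac < 1):
        raise ValidationError(f"margin_frac must be in (0,1), got {margin_frac}")
    keep = _rim_keep_mask((image.height, image.width), retina, margin_frac)
    out = np.where(keep[..., None], image.pixels, np.uint8(0))
    return FundusImage(out, image.image_id, image.original_size)


def _binarize_gray(gray: np.ndarray, top_bright_frac: float) -> np.ndarray:
    nz = gray[gray > 0]
    if nz.size < 100:
        raise ValidationError(f"image too dark: only {nz.size} nonzero pixels (need >= 100)")
    k = max(1, int(np.ceil(top_bright_frac * nz.size)))
    top = np.partition(nz, nz.size - k)[nz.size - k:]
    threshold = top.mean()
    return gray >= threshold


def adaptive_binarize(image: FundusImage, top_bright_frac: float = 0.01) -> np.ndarray:
    """Binary mask of pixels at least as bright as the top-1% mean.

    The threshold is the mean luminance of the brightest ``top_bright_frac``
    of *nonzero* pixels (zeros are the cropped-away background, not signal).
    On a typical fundus image only the OD core survives.
    """
    return _binarize_gray(image.grayscale(), top_bright_frac)


def clean_mask(mask: np.ndarray, erode_radius: int, dilate_radius: int) -> np.ndarray:
    """Disc-structuring-element erosion then dilation.

    Erosion removes components smaller than the element (reflective specks,
    impulse noise); dilation reconnects the disc core that vessels split
    into nearby fragments.  Radius 0 skips the corresponding step.  The
    morphology runs on the mask's tight bounding window for speed; the
    result is identical to operating on the full frame.
    """
    if erode_radius < 0 or dilate_radius < 0:
        raise ValidationError("morphology radii must be >= 0")
    if erode_radius == 0 and dilate_radius == 0:
        return mask.copy()
    out = np.zeros_like(mask)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return out
    pad = erode_radius + dilate_radius + 1
    y0, y1 = max(0, ys.min() - pad), min(mask.shape[0], ys.max() + pad + 1)
    x0, x1 = max(0, xs.min() - pad), min(mask.shape[1], xs.max() + pad + 1)
    window = mask[y0:y1, x0:x1]
    if erode_radius > 0:
        window = ndimage.binary_erosion(window, structure=morphology.disk(erode_radius))
    if dilate_radius > 0:
        window = ndimage.binary_dilation(window, structure=morphology.disk(dilate_radius))
    out[y0:y1, x0:x1] = window
    return out


def propose_od(mask: np.ndarray, config: HeuristicConfig | None = None) -> CircleProposal:
    """Largest connected component -> centroid + inflated equivalent radius.

    The returned radius is ``proposal_scale * sqrt(area / pi)`` — a circle
    deliberately larger than the measured blob, since the thresholded core
    underestimates the true disc.  Ties in area break toward the smaller
    ``(cy, cx)`` centroid for determinism.
    """
    config = config or HeuristicConfig()
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise NoDiscCandidateError("no disc candidate: mask is empty")
    # label only the tight nonzero window; centroids get the offset back
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    window = mask[y0:y1, x0:x1]
    labels, n_comp = ndimage.label(window)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n_comp + 1))
    centroids = [
        (cy + y0, cx + x0)
        for cy, cx in ndimage.center_of_mass(window, labels, index=range(1, n_comp + 1))
    ]
    order = sorted(
        range(n_comp),
        key=lambda i: (-areas[i], centroids[i][0], centroids[i][1]),
    )
    best = order[0]
    if areas[best] < config.min_blob_area:
        raise NoDiscCandidateError(
            f"no disc candidate: largest blob area {int(areas[best])} px "
            f"< min_blob_area {config.min_blob_area}"
        )
    cy, cx = centroids[best]
    raw_r = float(np.sqrt(areas[best] / np.pi))
    return CircleProposal(cx=float(cx), cy=float(cy), r=config.proposal_scale * raw_r)


def _fallback_proposal(gray: np.ndarray, retina: CircleProposal,
                       top_bright_frac: float) -> CircleProposal:
    """Brightest-1%-pixel centroid with r = 0.1 x retina radius."""
    nz_idx = np.nonzero(gray > 0)
    vals = gray[nz_idx]
    k = max(1, int(np.ceil(top_bright_frac * vals.size)))
    sel = np.argpartition(vals, vals.size - k)[vals.size - k:]
    cy = float(nz_idx[0][sel].mean())
    cx = float(nz_idx[1][sel].mean())
    return CircleProposal(cx=cx, cy=cy, r=0.1 * retina.r)


def localize(image: FundusImage, config: HeuristicConfig | None = None) -> LocalizationResult:
    """Run the full pipeline; returns circle + box in original coordinates.

    The image is resampled (bilinear) to a ``working_size`` square, so the
    crop margin, morphology radii and blob-area floor mean the same thing at
    every input resolution; the proposal is mapped back with the independent
    x/y scale factors (radius with their mean) and the box is the tight
    square of the mapped circle clipped to the frame.
    """
    config = config or HeuristicConfig()
    h, w = image.height, image.width
    ws = config.working_size
    # luminance first, then a single-channel resize: the whole pipeline is
    # grayscale, so resampling three channels would be wasted work
    gray = image.grayscale().astype(np.float32)
    if (h, w) != (ws, ws):
        gray = transform.resize(
            gray, (ws, ws), order=1, mode="reflect",
            anti_aliasing=False, preserve_range=True,
        ).astype(np.float32)

    retina = _estimate_retina_gray(gray)
    keep = _rim_keep_mask(gray.shape, retina, config.crop_margin_frac)
    cropped = np.where(keep, gray, np.float32(0))
    mask = _binarize_gray(cropped, config.top_bright_frac)
    mask = clean_mask(mask, config.erode_radius, config.dilate_radius)

    confidence = "normal"
    try:
        circle = propose_od(mask, config)
        if (config.max_disc_radius_frac is not None
                and circle.r > config.max_disc_radius_frac * retina.r):
            raise NoDiscCandidateError(
                f"proposal radius {circle.r:.0f} px exceeds sanity bound "
                f"{config.max_disc_radius_frac:.2f} x retina radius"
            )
    except NoDiscCandidateError:
        circle = _fallback_proposal(cropped, retina, config.top_bright_frac)
        confidence = "low"

    sx, sy = w / ws, h / ws
    mapped = CircleProposal(
        cx=circle.cx * sx, cy=circle.cy * sy, r=circle.r * (sx + sy) / 2.0
    )
    box = mapped.to_box(height=h, width=w)
    return LocalizationResult(circle=mapped, box=box, confidence=confidence,
                              image_id=image.image_id)
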