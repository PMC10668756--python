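"""Four-stage comet segmentation: preprocess, locate, head, tail.

The pipeline mirrors how an operator reads a comet-assay micrograph:

1. **Preprocessing** — grayscale morphological opening then closing removes
   salt noise and fills pinholes without shifting region boundaries.
2. **Candidate location** — comets are brighter than the background, so a
   global Otsu threshold (plus a configurable offset for dim slides)
   binarizes the image; 8-connected components within an area window become
   candidate regions.
3. **Head segmentation** — within each candidate the head is the brightest
   blob; a second, region-restricted Otsu threshold isolates it, and shape
   constraints (area window, circularity 4πA/P², convexity A / hull area)
   reject non-head blobs.
4. **Tail segmentation** — the candidate region is smoothed by closing and
   its convex hull taken; the hull minus the head, restricted to the
   smoothed region, is the tail.

A trained decision tree then decides tailed vs head-only (emptying the tail
of intact cells), and geometric filters discard comets with an implausible
head/tail area ratio or a migration axis not parallel to x (electrophoresis
direction).  Everything is deterministic: no stage draws random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from skimage import measure, morphology
from skimage.filters import apply_hysteresis_threshold, threshold_multiotsu, threshold_otsu
from skimage.morphology import convex_hull_image

from . import classification
from .image_io import IntensityImage

__all__ = [
    "SegConfig",
    "Region",
    "CometSegmentation",
    "preprocess",
    "locate_candidates",
    "segment_head",
    "segment_tail",
    "apply_geometric_filters",
    "segment_image",
]

DiscardReason = Literal["none", "ratio", "orientation", "no_head"]


@dataclass(frozen=True)
class SegConfig:
    """Tunable parameters of the segmentation pipeline.

    All defaults are implementation calibration, sized for heads of radius
    ~8–15 px; none are measured constants of the assay.
    """

    noise_element_size: int = 3  # square side, px, for opening/closing
    threshold_offset: float = 0.0  # added to the global Otsu threshold
    min_candidate_area: int = 30
    max_candidate_area: int = 50_000
    min_head_area: int = 30
    max_head_area: int = 5_000
    min_circularity: float = 0.7
    min_convexity: float = 0.9
    ratio_interval: tuple[float, float] = (0.05, 20.0)  # head/tail area ratio
    max_angle_deg: float = 20.0  # |axis angle| vs +x tolerated
    tail_smooth_size: int = 5  # closing element for tail smoothing

    def __post_init__(self) -> None:
        if not 0 < self.min_circularity <= 1 or not 0 < self.min_convexity <= 1:
            raise ValueError("circularity/convexity thresholds must lie in (0, 1]")
        if self.min_candidate_area <= 0 or self.max_candidate_area < self.min_candidate_area:
            raise ValueError("candidate area bounds must be positive and ordered")
        if self.min_head_area <= 0 or self.max_head_area < self.min_head_area:
            raise ValueError("head area bounds must be positive and ordered")


@dataclass
class Region:
    """An 8-connected candidate component from the location stage."""

    mask: np.ndarray  # full-image boolean support
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) exclusive
    area: int
    centroid: tuple[float, float]  # (row, col)


@dataclass
class CometSegmentation:
    """Head/tail masks and accept status for one candidate region."""

    region_id: int
    head_mask: np.ndarray
    tail_mask: np.ndarray
    has_tail: bool
    accepted: bool = True
    discard_reason: DiscardReason = "none"
    features: classification.CometFeatures | None = None


def _square(size: int) -> np.ndarray:
    return morphology.footprint_rectangle((size, size))


def preprocess(image: IntensityImage, config: SegConfig | None = None) -> IntensityImage:
    """Morphological opening then closing with the configured square element."""
    cfg = config or SegConfig()
    if cfg.noise_element_size > min(image.height, image.width):
        raise ValueError(
            f"noise element ({cfg.noise_element_size}px) larger than image "
            f"{image.width}x{image.height}"
        )
    fp = _square(cfg.noise_element_size)
    out = morphology.closing(morphology.opening(image.pixels, fp), fp)
    return IntensityImage(out, bit_depth=image.bit_depth)


def locate_candidates(image: IntensityImage, config: SegConfig | None = None) -> list[Region]:
    """Threshold globally (Otsu + offset) and label 8-connected components.

    Components outside the configured area window are dropped; the survivors
    are returned sorted by centroid in row-major order.
    """
    cfg = config or SegConfig()
    pixels = image.pixels
    if pixels.min() == pixels.max():
        return []
    # three-class between-class-variance maximisation: comet images carry
    # three intensity populations (background, dim tails, bright heads); the
    # lower threshold separates background from comet.  Falls back to plain
    # two-class Otsu when the histogram is too sparse to split three ways.
    try:
        thr = threshold_multiotsu(pixels, classes=3)[0] + cfg.threshold_offset
    except ValueError:
        thr = threshold_otsu(pixels) + cfg.threshold_offset
    # hysteresis: comets seed above the global threshold and extend down to
    # just above the background, so dim tail ends connected to a bright seed
    # are kept while isolated background fluctuations are not.
    dark = pixels[pixels <= thr].astype(float)
    bg_level = np.median(dark)
    bg_sigma = 1.4826 * np.median(np.abs(dark - bg_level))  # robust sigma
    low = bg_level + 2.0 * bg_sigma + cfg.threshold_offset
    if low >= thr:
        binary = pixels > thr
    else:
        binary = apply_hysteresis_threshold(pixels.astype(float), low, thr)
    labels = measure.label(binary, connectivity=2)
    regions = []
    for prop in measure.regionprops(labels):
        if not cfg.min_candidate_area <= prop.area <= cfg.max_candidate_area:
            continue
        regions.append(
            Region(
                mask=labels == prop.label,
                bbox=tuple(prop.bbox),
                area=int(prop.area),
                centroid=tuple(prop.centroid),
            )
        )
    regions.sort(key=lambda r: r.centroid)
    return regions


def _circularity(blob: np.ndarray) -> float:
    props = measure.regionprops(blob.astype(np.uint8))[0]
    perim = props.perimeter
    if perim == 0:
        return 1.0
    # digital discs can overshoot 1 slightly with chain-code perimeters
    return float(min(1.0, 4.0 * np.pi * props.area / perim**2))


def _convexity(blob: np.ndarray) -> float:
    props = measure.regionprops(blob.astype(np.uint8))[0]
    return float(props.solidity)


def _brightest_blob(bright: np.ndarray, pixels: np.ndarray, fp: np.ndarray) -> np.ndarray | None:
    """Highest-mean-intensity connected blob, fringe shaved by opening/closing."""
    labels = measure.label(bright, connectivity=2)
    if labels.max() == 0:
        return None
    prop = max(measure.regionprops(labels, intensity_image=pixels), key=lambda p: p.intensity_mean)
    blob = labels == prop.label
    smooth = morphology.closing(morphology.opening(blob, fp), fp)
    return smooth if smooth.any() else blob


def segment_head(
    image: IntensityImage, region: Region, config: SegConfig | None = None
) -> np.ndarray | None:
    """Isolate the head: region-restricted thresholding plus shape gates.

    The head is the brightest compact spot of the candidate region, but no
    single threshold isolates it in every case: an undamaged cell's region
    *is* its head (best threshold: none at all), while a heavily damaged
    comet has a tail nearly as bright as the head (best threshold: high).
    So a sweep of region-restricted thresholds — the region's Otsu value
    plus a ladder of intensity quantiles — proposes brightest-blob
    candidates, each checked against the area window, circularity
    (4πA/P², chain-code perimeter) and convexity (A / convex-hull area)
    gates; the largest passing blob is the head.  Returns ``None`` when no
    threshold yields an acceptable blob (the "no head" outcome).
    """
    cfg = config or SegConfig()
    pixels = image.pixels
    vals = pixels[region.mask]
    fp = _square(cfg.noise_element_size)

    thresholds: list[float] = [float(vals.min()) - 1.0]  # no split: whole region
    if np.unique(vals).size > 1:
        thresholds.append(float(threshold_otsu(vals)))
        thresholds += [float(q) for q in np.quantile(vals, (0.3, 0.5, 0.7, 0.8, 0.9))]

    best: np.ndarray | None = None
    for thr in sorted(set(thresholds)):
        blob = _brightest_blob(region.mask & (pixels > thr), pixels, fp)
        if blob is None:
            continue
        area = int(blob.sum())
        if not cfg.min_head_area <= area <= cfg.max_head_area:
            continue
        if _circularity(blob) < cfg.min_circularity:
            continue
        if _convexity(blob) < cfg.min_convexity:
            continue
        if best is None or area > best.sum():
            best = blob
    if best is None:
        return None
    if best.sum() < 0.9 * region.area:
        best = _grow_head_disc(best, region, cfg)
    return best


def _grow_head_disc(core: np.ndarray, region: Region, cfg: SegConfig) -> np.ndarray:
    """Expand a bright head core to the full head disc.

    A high threshold may keep only the head's bright centre, leaving its
    dimmer rim to be miscounted as tail.  Heads are near-circular (the
    shape gates enforce it), so the full disc is reconstructed from the
    region's vertical chord through the core centroid: at the head the
    region spans the head diameter, while the tail band is narrower.  The
    estimated disc, clipped to the region, becomes the head whenever it
    covers the core.
    """
    rows, cols = np.nonzero(core)
    cy, cx = rows.mean(), cols.mean()
    near = np.abs(np.nonzero(region.mask)[1] - cx) <= 2
    chord_rows = np.nonzero(region.mask)[0][near]
    if chord_rows.size == 0:
        return core
    r_hat = (chord_rows.max() - chord_rows.min() + 1) / 2.0
    centre_row = (chord_rows.max() + chord_rows.min()) / 2.0
    yy, xx = np.mgrid[0 : region.mask.shape[0], 0 : region.mask.shape[1]]
    disc = ((yy - centre_row) ** 2 + (xx - cx) ** 2 <= r_hat**2) & region.mask
    return disc if (core & ~disc).sum() <= 0.1 * core.sum() else core


def segment_tail(
    image: IntensityImage,
    region: Region,
    head: np.ndarray,
    config: SegConfig | None = None,
) -> np.ndarray:
    """Tail = convex hull of the smoothed region, minus the head.

    The hull is intersected with the smoothed region support so background
    inside the hull's slack does not enter the tail; the result may be empty
    (head-only cells).
    """
    cfg = config or SegConfig()
    smoothed = morphology.closing(region.mask, _square(cfg.tail_smooth_size))
    hull = convex_hull_image(smoothed) if smoothed.any() else smoothed
    return hull & smoothed & ~head


def _axis_angle_deg(head: np.ndarray, tail: np.ndarray) -> float:
    """Angle of the head-centroid -> farthest-tail-pixel vector vs +x."""
    hy, hx = np.nonzero(head)
    cy, cx = hy.mean(), hx.mean()
    ty, tx = np.nonzero(tail)
    d2 = (tx - cx) ** 2 + (ty - cy) ** 2
    k = int(np.argmax(d2))
    return float(np.degrees(np.arctan2(ty[k] - cy, tx[k] - cx)))


def apply_geometric_filters(
    seg: CometSegmentation, config: SegConfig | None = None
) -> CometSegmentation:
    """Discard comets with an implausible head/tail ratio or migration angle.

    Head-only cells are exempt from both tests (there is no tail to measure
    a ratio or an axis against).
    """
    cfg = config or SegConfig()
    if not seg.has_tail or not seg.tail_mask.any():
        return seg
    ratio = seg.head_mask.sum() / seg.tail_mask.sum()
    lo, hi = cfg.ratio_interval
    if not lo <= ratio <= hi:
        return replace(seg, accepted=False, discard_reason="ratio")
    if abs(_axis_angle_deg(seg.head_mask, seg.tail_mask)) > cfg.max_angle_deg:
        return replace(seg, accepted=False, discard_reason="orientation")
    return seg


def segment_image(
    image: IntensityImage,
    config: SegConfig | None = None,
    model: classification.DecisionTreeModel | None = None,
) -> list[CometSegmentation]:
    """Run the full pipeline on one micrograph.

    Per-region failures (no acceptable head) are reported as discarded
    segmentations rather than aborting the remaining regions.  Deterministic
    for fixed inputs.
    """
    cfg = config or SegConfig()
    tree = model if model is not None else classification.default_model()
    pre = preprocess(image, cfg)
    results: list[CometSegmentation] = []
    for i, region in enumerate(locate_candidates(pre, cfg)):
        head = segment_head(pre, region, cfg)
        if head is None:
            results.append(
                CometSegmentation(
                    region_id=i,
                    head_mask=region.mask & False,
                    tail_mask=region.mask & False,
                    has_tail=False,
                    accepted=False,
                    discard_reason="no_head",
                )
            )
            continue
        tail = segment_tail(pre, region, head, cfg)
        feats = classification.extract_features(pre, head, tail)
        tailed = classification.predict(tree, feats) == classification.TAILED
        if not tailed:
            tail = np.zeros_like(tail)
        seg = CometSegmentation(
            region_id=i,
            head_mask=head,
            tail_mask=tail,
            has_tail=tailed,
            features=feats,
        )
        results.append(apply_geometric_filters(seg, cfg))
    return results
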