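"""Synthetic comet-assay image generation with exact ground truth.

Real comet micrographs show a bright, near-circular "head" (the compact
nucleoid) and, for cells with fragmented DNA, a dimmer "tail" of migrated
DNA extending in the electrophoresis direction (canonically +x here).  The
generator renders each comet as:

* head — an isotropic Gaussian intensity disc truncated at the head radius;
* tail — a band of configurable length starting at the head boundary, with
  exponential intensity decay along its axis and a Gaussian cross profile,
  tilted by a small random angle about the +x axis.

Head and tail components are rescaled so that the integrated tail intensity
over the integrated total equals a drawn "tail DNA fraction" — the quantity
the tail-moment statistic downstream is built on — making every comet its
own quantification ground truth.  A constant background plus i.i.d.
Gaussian read noise is added last.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64, so a seed fully determines the scene on any platform.  Per scene the
draw order is fixed and documented in :func:`generate_assay_image`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .image_io import IntensityImage

__all__ = [
    "SynthConfig",
    "GroundTruthComet",
    "PlacementError",
    "generate_assay_image",
    "generate_labeled_feature_set",
    "generate_piecewise_dataset",
]


class PlacementError(RuntimeError):
    """Requested comets cannot be placed under the spacing constraint."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic comet-assay scene.

    Intensity units are raw camera counts at the configured bit depth;
    lengths are pixels; angles degrees.
    """

    width: int = 512
    height: int = 512
    bit_depth: int = 8
    background: float = 12.0
    noise_sigma: float = 3.0
    n_comets: int = 8
    head_radius: tuple[float, float] = (8.0, 14.0)
    head_peak: tuple[float, float] = (150.0, 220.0)
    tail_probability: float = 0.5
    tail_length: tuple[float, float] = (60.0, 110.0)
    tail_fraction: tuple[float, float] = (0.3, 0.7)
    tail_decay: float = 120.0  # exponential length constant, px
    orientation_jitter: float = 8.0  # max |angle| about +x, degrees
    min_spacing: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("head_radius", "head_peak", "tail_length", "tail_fraction"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} range reversed: {(lo, hi)}")
        if not (0.0 <= self.tail_fraction[0] and self.tail_fraction[1] <= 1.0):
            raise ValueError("tail_fraction range must lie within [0, 1]")
        if not 0.0 <= self.tail_probability <= 1.0:
            raise ValueError("tail_probability outside [0, 1]")


@dataclass
class GroundTruthComet:
    """Exact per-comet ground truth emitted alongside a synthetic image.

    ``head_dna``/``tail_dna`` are integrated noiseless intensities over the
    respective masks, so ``head_dna + tail_dna`` is the comet's total drawn
    intensity and ``tail_dna / (head_dna + tail_dna)`` reproduces
    ``tail_dna_fraction`` up to pixel discretization.
    """

    head_mask: np.ndarray
    tail_mask: np.ndarray
    has_tail: bool
    tail_length: float  # x-extent from head's rightmost to tail's rightmost column
    tail_dna_fraction: float  # the drawn fraction (0 when no tail)
    head_dna: float
    tail_dna: float

    @property
    def tail_moment(self) -> float:
        return self.tail_length * self.tail_dna_fraction


def _render_comet(cfg: SynthConfig, cx, cy, radius, peak, has_tail, length, fraction, angle_deg):
    """Render one comet onto a fresh float canvas; return (canvas, head, tail)."""
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - cx, yy - cy

    sigma_h = radius  # flat-topped profile: edge intensity ~0.6 of the peak
    dist2 = dx * dx + dy * dy
    head_mask = dist2 <= radius * radius
    head = np.where(head_mask, np.exp(-dist2 / (2.0 * sigma_h**2)), 0.0)
    head *= peak  # peak normalised to 1 at the centre by construction
    head_sum = head.sum()

    canvas = head.copy()
    tail_mask = np.zeros_like(head_mask)
    if has_tail and fraction > 0:
        theta = np.deg2rad(angle_deg)
        ux, uy = np.cos(theta), np.sin(theta)
        s = dx * ux + dy * uy - (radius + 1.0)  # along-axis, 0 at head boundary
        t = -dx * uy + dy * ux  # cross-axis
        half_width = max(2.0, 0.55 * radius)
        band = (s >= 0) & (s <= length) & (np.abs(t) <= half_width) & ~head_mask
        # near-uniform cross profile (gentle falloff at the band edge) with
        # exponential decay along the migration axis
        profile = np.where(
            band, np.exp(-s / cfg.tail_decay) * np.exp(-((t / half_width) ** 4)), 0.0
        )
        target = fraction / (1.0 - fraction) * head_sum
        profile *= target / profile.sum()
        # drop sub-quantisation pixels so mask support matches rendered support
        tail_mask = profile >= 0.5
        profile = np.where(tail_mask, profile, 0.0)
        canvas += profile
    return canvas, head_mask, tail_mask


def _tail_x_extent(head_mask: np.ndarray, tail_mask: np.ndarray) -> float:
    if not tail_mask.any():
        return 0.0
    head_right = np.max(np.nonzero(head_mask.any(axis=0))[0])
    tail_right = np.max(np.nonzero(tail_mask.any(axis=0))[0])
    return float(max(0, tail_right - head_right))


def generate_assay_image(config: SynthConfig) -> tuple[IntensityImage, list[GroundTruthComet]]:
    """Generate one synthetic micrograph and its per-comet ground truth.

    Draw order (fixed for reproducibility): (1) one Bernoulli(tail_probability)
    per comet via ``rng.random(n) < p``; (2) per comet, in index order:
    radius, peak, tail length, tail fraction, orientation; (3) per comet,
    candidate centre positions until placement succeeds; (4) the Gaussian
    noise field.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_comets

    has_tail = rng.random(n) < cfg.tail_probability
    params = []
    for i in range(n):
        radius = rng.uniform(*cfg.head_radius)
        peak = rng.uniform(*cfg.head_peak)
        length = rng.uniform(*cfg.tail_length)
        fraction = rng.uniform(*cfg.tail_fraction)
        angle = rng.uniform(-cfg.orientation_jitter, cfg.orientation_jitter)
        params.append((radius, peak, length, fraction, angle))

    # rejection-sample centres so expanded bounding boxes never overlap
    boxes: list[tuple[float, float, float, float]] = []
    centres = []
    for i in range(n):
        radius, peak, length, fraction, angle = params[i]
        extent_x = radius + 2 + (length + 3 if has_tail[i] else 0)
        extent_y = max(radius, 0.8 * radius + abs(length * np.sin(np.deg2rad(cfg.orientation_jitter)))) + 2
        placed = False
        if cfg.width - extent_x <= radius + 2 or cfg.height <= 2 * extent_y:
            raise PlacementError(
                f"comet {i + 1}/{n} (extent {extent_x:.0f}x{2 * extent_y:.0f}px, "
                f"min_spacing={cfg.min_spacing}) cannot fit a {cfg.width}x{cfg.height} image"
            )
        for _ in range(2000):
            cx = rng.uniform(radius + 2, cfg.width - extent_x)
            cy = rng.uniform(extent_y, cfg.height - extent_y)
            box = (cx - radius - 2, cy - extent_y, cx + extent_x, cy + extent_y)
            pad = cfg.min_spacing
            ok = all(
                box[2] + pad < b[0] or b[2] + pad < box[0] or box[3] + pad < b[1] or b[3] + pad < box[1]
                for b in boxes
            )
            if ok:
                boxes.append(box)
                centres.append((cx, cy))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place comet {i + 1}/{n} under min_spacing={cfg.min_spacing} "
                f"in a {cfg.width}x{cfg.height} image"
            )

    noiseless = np.zeros((cfg.height, cfg.width), float)
    truth: list[GroundTruthComet] = []
    for i in range(n):
        radius, peak, length, fraction, angle = params[i]
        cx, cy = centres[i]
        canvas, head_mask, tail_mask = _render_comet(
            cfg, cx, cy, radius, peak, bool(has_tail[i]), length, fraction, angle
        )
        rounded = np.round(canvas)
        noiseless += rounded
        truth.append(
            GroundTruthComet(
                head_mask=head_mask,
                tail_mask=tail_mask,
                has_tail=bool(has_tail[i]),
                tail_length=_tail_x_extent(head_mask, tail_mask),
                tail_dna_fraction=float(fraction) if has_tail[i] else 0.0,
                head_dna=float(rounded[head_mask].sum()),
                tail_dna=float(rounded[tail_mask].sum()),
            )
        )

    noisy = noiseless + cfg.background + rng.normal(0.0, cfg.noise_sigma, noiseless.shape)
    maxval = 2**cfg.bit_depth - 1
    pixels = np.clip(np.round(noisy), 0, maxval)
    return IntensityImage(pixels, bit_depth=cfg.bit_depth), truth


_PATCH = SynthConfig(width=192, height=96, n_comets=1, min_spacing=4.0)


def generate_labeled_feature_set(n: int, config: SynthConfig | None = None, seed: int = 0):
    """Render ``n`` single-comet patches and extract classifier features.

    Labels come from the generator's ground truth (``True`` = tailed comet).
    For head-only cells the tail-candidate mask emulates the convex-hull
    slack the segmentation stage produces: a one-pixel ring around the head.

    Returns ``(features, labels)`` where ``features`` is a list of
    :class:`~cometkit.classification.CometFeatures`.
    """
    from scipy import ndimage

    from .classification import extract_features

    cfg = config if config is not None else _PATCH
    if cfg.n_comets != 1:
        raise ValueError("feature-set generation renders one comet per patch")
    features, labels = [], []
    for i in range(n):
        image, (gt,) = generate_assay_image(replace(cfg, seed=seed * 1_000_003 % 2**31 + i))
        if gt.has_tail:
            candidate = gt.tail_mask
        else:
            candidate = ndimage.binary_dilation(gt.head_mask) & ~gt.head_mask
        features.append(extract_features(image, gt.head_mask, candidate))
        labels.append(gt.has_tail)
    if len(set(labels)) < 2 and n >= 2:
        raise ValueError("single-class draw; choose another seed or tail_probability")
    return features, labels


def generate_piecewise_dataset(
    intercept: float,
    slope1: float,
    slope2: float,
    breakpoint: float,
    noise_sigma: float,
    x: Sequence[float],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a continuous one-breakpoint broken-line response.

    ``y = intercept + slope1*x`` up to the breakpoint, continuing with
    ``slope2`` beyond it (continuous at the breakpoint), plus i.i.d.
    Gaussian noise.
    """
    x = np.asarray(x, float)
    if not x.min() < breakpoint < x.max():
        raise ValueError(f"breakpoint {breakpoint} outside the open x range ({x.min()}, {x.max()})")
    y = intercept + slope1 * x + (slope2 - slope1) * np.maximum(x - breakpoint, 0.0)
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma, x.shape)
    return x, y
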