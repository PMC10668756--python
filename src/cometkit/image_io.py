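"""Reading and writing images, masks, projects, and tabular results.

The analysed unit is a single grayscale fluorescence micrograph of
SYBR-stained nucleoids ("comets").  Images are stored as
:class:`IntensityImage`, a thin wrapper around a 2-D integer array with an
explicit bit depth.  Segmentation results are persisted as a JSON
:class:`Project` (diff-able, language-portable), per-comet measurements as a
CSV table, and masks as 8-bit label PNGs (0 = background, 1 = head,
2 = tail).

Coordinate convention: origin at the top-left pixel, 0-based indices,
x grows rightward (columns), y grows downward (rows).  Polygon contours are
lists of ``(x, y)`` vertices that close implicitly (last vertex connects
back to the first).
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "IntensityImage",
    "Project",
    "ProjectComet",
    "FemaleRecord",
    "SchemaVersionError",
    "UnsupportedImageError",
    "PROJECT_SCHEMA_VERSION",
    "read_image",
    "write_image",
    "write_label_mask",
    "read_label_mask",
    "save_project",
    "load_project",
    "export_metrics_csv",
    "load_female_table",
    "mask_to_contour",
    "contour_to_mask",
    "mask_to_rle",
    "rle_to_mask",
]

PROJECT_SCHEMA_VERSION = 1

#: fixed column order of the metrics CSV
METRICS_COLUMNS = (
    "image_id",
    "comet_id",
    "head_area",
    "tail_area",
    "head_dna",
    "tail_dna",
    "tail_dna_fraction",
    "tail_length_px",
    "tail_moment",
    "accepted",
    "discard_reason",
)


class UnsupportedImageError(ValueError):
    """Raised for images the pipeline cannot interpret as single-channel."""


class SchemaVersionError(ValueError):
    """Raised when a project file carries an unknown schema version."""


@dataclass(frozen=True)
class IntensityImage:
    """A 2-D grid of non-negative pixel intensities with a bit depth.

    Parameters
    ----------
    pixels
        ``(height, width)`` array of unsigned integers.
    bit_depth
        8 or 16; all values must lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ValueError("pixel values outside bit-depth range")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        object.__setattr__(self, "pixels", px.astype(dtype))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ProjectComet:
    """One segmented comet stored in a project: closed contours plus flags.

    ``contour`` outlines the whole comet; ``head_contour``/``tail_contour``
    outline its parts (tail contour empty for head-only cells).
    """

    contour: list[tuple[float, float]]  # (x, y) vertices, implicit closure
    head_contour: list[tuple[float, float]] = field(default_factory=list)
    tail_contour: list[tuple[float, float]] = field(default_factory=list)
    manual: bool = False
    accepted: bool = True
    discard_reason: str = "none"


@dataclass
class Project:
    """A segmentation session: image references and per-image comet contours.

    Manual edits (``manual=True`` comets) are never overwritten when the
    automatic pipeline is re-run through :meth:`replace_automatic`.
    """

    images: dict[str, dict] = field(default_factory=dict)  # id -> {path, sha256}
    comets: dict[str, list[ProjectComet]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    schema_version: int = PROJECT_SCHEMA_VERSION

    def add_image(self, image_id: str, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.images[image_id] = {"path": str(path), "sha256": digest}
        self.comets.setdefault(image_id, [])

    def replace_automatic(self, image_id: str, new: Sequence[ProjectComet]) -> None:
        """Replace automatically generated comets, preserving manual edits."""
        kept = [c for c in self.comets.get(image_id, []) if c.manual]
        self.comets[image_id] = kept + list(new)


def read_image(path: str | Path) -> IntensityImage:
    """Read a grayscale 8- or 16-bit TIFF or PNG micrograph.

    RGB images whose channels are identical are collapsed to one channel;
    genuinely multichannel images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0 or arr.ndim < 2:
        raise IOError(f"could not read image {path}: no image data (truncated or corrupt)")
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            rgb = arr[..., :3]
            if not (np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 0], rgb[..., 2])):
                raise UnsupportedImageError(f"{path}: multichannel image with non-identical channels")
            arr = rgb[..., 0]
        else:
            raise UnsupportedImageError(f"{path}: unsupported shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedImageError(f"{path}: unsupported dtype {arr.dtype}")
    return IntensityImage(arr, bit_depth=depth)


def write_image(image: IntensityImage, path: str | Path) -> None:
    """Write an :class:`IntensityImage` as TIFF or PNG (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def write_label_mask(head: np.ndarray, tail: np.ndarray, path: str | Path) -> None:
    """Write head/tail masks as an 8-bit label PNG (0 bg, 1 head, 2 tail)."""
    label = np.zeros(head.shape, dtype=np.uint8)
    label[np.asarray(tail, bool)] = 2
    label[np.asarray(head, bool)] = 1
    iio.imwrite(Path(path), label)


def read_label_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a label PNG back into (head, tail) boolean masks."""
    label = np.asarray(iio.imread(Path(path)))
    return label == 1, label == 2


def save_project(project: Project, path: str | Path) -> None:
    """Serialize a project losslessly to a single JSON document."""
    doc = {
        "schema_version": project.schema_version,
        "images": project.images,
        "config": project.config,
        "comets": {
            image_id: [
                {
                    "contour": [[float(x), float(y)] for x, y in c.contour],
                    "head_contour": [[float(x), float(y)] for x, y in c.head_contour],
                    "tail_contour": [[float(x), float(y)] for x, y in c.tail_contour],
                    "manual": c.manual,
                    "accepted": c.accepted,
                    "discard_reason": c.discard_reason,
                }
                for c in comets
            ]
            for image_id, comets in project.comets.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_project(path: str | Path) -> Project:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    version = doc.get("schema_version")
    if version != PROJECT_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"project schema version {version!r} not supported (expected {PROJECT_SCHEMA_VERSION})"
        )
    project = Project(images=doc.get("images", {}), config=doc.get("config", {}))
    for image_id, comets in doc.get("comets", {}).items():
        project.comets[image_id] = [
            ProjectComet(
                contour=[(float(x), float(y)) for x, y in c["contour"]],
                head_contour=[(float(x), float(y)) for x, y in c.get("head_contour", [])],
                tail_contour=[(float(x), float(y)) for x, y in c.get("tail_contour", [])],
                manual=bool(c["manual"]),
                accepted=bool(c["accepted"]),
                discard_reason=str(c["discard_reason"]),
            )
            for c in comets
        ]
    return project


def export_metrics_csv(metrics: Sequence, path: str | Path) -> None:
    """Write per-comet measurements as UTF-8 CSV in a fixed column order.

    ``metrics`` holds objects (e.g. ``CometMetrics``) or mappings exposing
    the :data:`METRICS_COLUMNS` fields.
    """
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(METRICS_COLUMNS)
        for m in metrics:
            get = m.get if isinstance(m, dict) else lambda k, _m=m: getattr(_m, k)
            writer.writerow([get(col) for col in METRICS_COLUMNS])


@dataclass(frozen=True)
class FemaleRecord:
    """One female: storage time (months) of the stored sperm and its viability (%)."""

    individual_id: str
    trial_id: str
    storage_time: float
    viability: float

    def __post_init__(self) -> None:
        if self.storage_time < 0:
            raise ValueError(f"{self.individual_id}: negative storage time")
        if not 0 <= self.viability <= 100:
            raise ValueError(
                f"{self.individual_id}: viability {self.viability} outside [0, 100]"
            )


def load_female_table(path: str | Path | None = None) -> list[FemaleRecord]:
    """Load per-female storage time and sperm viability records.

    Without an argument, loads the packaged 30-female spider-crab table
    (storage times 0–14 months), preserving its printed order.
    """
    if path is None:
        source = resources.files("cometkit.data") / "table2.csv"
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.DictReader(text.splitlines()))
    required = {"individual", "trial", "storage_months", "viability"}
    if not rows or not required.issubset(rows[0].keys()):
        missing = required - set(rows[0].keys() if rows else ())
        raise ValueError(f"female table missing columns: {sorted(missing)}")
    return [
        FemaleRecord(
            individual_id=r["individual"],
            trial_id=r["trial"],
            storage_time=float(r["storage_months"]),
            viability=float(r["viability"]),
        )
        for r in rows
    ]


# --- mask <-> contour / run-length helpers (project and ground-truth files) ---


def mask_to_contour(mask: np.ndarray) -> list[tuple[float, float]]:
    """Outline a mask as a closed (x, y) polygon (longest iso-contour)."""
    from skimage import measure as _measure

    mask = np.asarray(mask, bool)
    if not mask.any():
        return []
    contours = _measure.find_contours(mask.astype(float), 0.5)
    rc = max(contours, key=len)
    return [(float(c), float(r)) for r, c in rc]


def contour_to_mask(contour: Sequence[tuple[float, float]], shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a closed (x, y) polygon back into a boolean mask."""
    from skimage import draw as _draw

    mask = np.zeros(shape, bool)
    if len(contour) < 3:
        return mask
    xs = np.array([p[0] for p in contour])
    ys = np.array([p[1] for p in contour])
    rr, cc = _draw.polygon(ys, xs, shape=shape)
    mask[rr, cc] = True
    return mask


def mask_to_rle(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major) for compact JSON storage."""
    mask = np.asarray(mask, bool)
    flat = mask.ravel()
    edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate([[0], edges + 1, [flat.size]])
    runs = []
    for start, stop in zip(bounds[:-1], bounds[1:]):
        if flat[start]:
            runs.extend([int(start), int(stop - start)])
    return {"shape": list(mask.shape), "runs": runs}


def rle_to_mask(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    flat = np.zeros(int(np.prod(shape)), bool)
    runs = rle["runs"]
    for start, length in zip(runs[::2], runs[1::2]):
        flat[start : start + length] = True
    return flat.reshape(shape)
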