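"""Decision-tree separation of tailed comets from head-only (undamaged) cells.

A candidate region that survives segmentation is either a degraded cell —
head plus tail — or an intact cell whose region contains only the head and
a sliver of background.  Four features separate the two cases: the head to
tail-candidate area ratio, the head's position along x within the region,
and the mean intensities of the head and tail-candidate pixels.

The classifier is a small CART tree: greedy binary splits minimising
weighted Gini impurity, with an exhaustive threshold search over the
midpoints of sorted unique feature values.  Ties between candidate splits
are broken by lowest feature index, then lowest threshold, which makes
training fully deterministic for a given sample.  Trees serialize to JSON.

The training set the original annotated micrographs would provide is not
distributed; the packaged default model is trained on the synthetic
generator (seed recorded in the model metadata), and retraining on user
annotations via :func:`train_tree` is a first-class operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CometFeatures",
    "DecisionTreeModel",
    "TreeNode",
    "FEATURE_NAMES",
    "RATIO_CAP",
    "extract_features",
    "train_tree",
    "predict",
    "train_default_model",
]

FEATURE_NAMES = (
    "head_tail_area_ratio",
    "head_relative_position",
    "mean_head_intensity",
    "mean_tail_intensity",
)

#: head/tail area ratio reported when the tail candidate is empty
RATIO_CAP = 100.0

TAILED = "tailed_comet"
HEAD_ONLY = "head_only"


@dataclass(frozen=True)
class CometFeatures:
    """The four shape/intensity features of one candidate region, fixed order."""

    head_tail_area_ratio: float
    head_relative_position: float  # in [-1, 1]; -1 = head at region's left edge
    mean_head_intensity: float
    mean_tail_intensity: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.head_tail_area_ratio,
                self.head_relative_position,
                self.mean_head_intensity,
                self.mean_tail_intensity,
            ]
        )


def extract_features(image, head: np.ndarray, tail_candidate: np.ndarray) -> CometFeatures:
    """Compute classifier features from an image and head/tail-candidate masks.

    ``image`` is an :class:`~cometkit.image_io.IntensityImage` or a bare 2-D
    array (the preprocessed intensities).  An empty tail candidate yields a
    zero mean tail intensity and the capped area ratio.
    """
    pixels = np.asarray(getattr(image, "pixels", image), float)
    head = np.asarray(head, bool)
    tail = np.asarray(tail_candidate, bool)
    if not head.any():
        raise ValueError("head mask is empty")

    head_area = int(head.sum())
    tail_area = int(tail.sum())
    ratio = head_area / tail_area if tail_area else RATIO_CAP

    region = head | tail
    cols = np.nonzero(region.any(axis=0))[0]
    x0, x1 = cols.min(), cols.max()
    head_cx = np.nonzero(head)[1].mean()
    position = 0.0 if x1 == x0 else 2.0 * (head_cx - x0) / (x1 - x0) - 1.0

    return CometFeatures(
        head_tail_area_ratio=float(min(ratio, RATIO_CAP)),
        head_relative_position=float(np.clip(position, -1.0, 1.0)),
        mean_head_intensity=float(pixels[head].mean()),
        mean_tail_intensity=float(pixels[tail].mean()) if tail_area else 0.0,
    )


@dataclass
class TreeNode:
    """Internal split node or leaf of a CART tree."""

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    klass: str | None = None  # set on leaves
    purity: float | None = None  # training purity of the leaf

    @property
    def is_leaf(self) -> bool:
        return self.klass is not None


@dataclass
class DecisionTreeModel:
    root: TreeNode
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(node: TreeNode):
            if node.is_leaf:
                return {"class": node.klass, "purity": node.purity}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return json.dumps({"tree": enc(self.root), "metadata": self.metadata}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTreeModel":
        def dec(obj) -> TreeNode:
            if "class" in obj:
                return TreeNode(klass=obj["class"], purity=obj.get("purity"))
            return TreeNode(
                feature=int(obj["feature"]),
                threshold=float(obj["threshold"]),
                left=dec(obj["left"]),
                right=dec(obj["right"]),
            )

        doc = json.loads(text)
        return cls(root=dec(doc["tree"]), metadata=doc.get("metadata", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "DecisionTreeModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _gini(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    p = labels.mean()
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray):
    """Exhaustive (feature, threshold) search minimising weighted child Gini.

    Ties resolve to the lowest feature index, then the lowest threshold.
    """
    n = y.size
    best = None  # (impurity, feature, threshold)
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        if vals.size < 2:
            continue
        for thr in (vals[:-1] + vals[1:]) / 2.0:
            mask = X[:, j] <= thr
            nl = mask.sum()
            imp = (nl * _gini(y[mask]) + (n - nl) * _gini(y[~mask])) / n
            key = (imp, j, thr)
            if best is None or key < best:
                best = key
    return best


def _grow(X: np.ndarray, y: np.ndarray, depth: int, depth_limit: int) -> TreeNode:
    p_tailed = y.mean()
    majority = TAILED if p_tailed >= 0.5 else HEAD_ONLY
    purity = float(max(p_tailed, 1.0 - p_tailed))
    if depth >= depth_limit or _gini(y) == 0.0:
        return TreeNode(klass=majority, purity=purity)
    best = _best_split(X, y)
    if best is None or best[0] >= _gini(y) - 1e-12:
        return TreeNode(klass=majority, purity=purity)
    _, j, thr = best
    mask = X[:, j] <= thr
    return TreeNode(
        feature=int(j),
        threshold=float(thr),
        left=_grow(X[mask], y[mask], depth + 1, depth_limit),
        right=_grow(X[~mask], y[~mask], depth + 1, depth_limit),
    )


def train_tree(features, labels, depth_limit: int = 3, seed: int = 0) -> DecisionTreeModel:
    """Train a CART tree on (CometFeatures, tailed?) pairs.

    ``labels`` are booleans (True = tailed comet) or the class-name strings.
    Training is deterministic: the seed is recorded in the metadata only.
    """
    X = np.array([f.as_array() for f in features], float)
    y = np.array([l == TAILED if isinstance(l, str) else bool(l) for l in labels], float)
    if y.size < 10:
        raise ValueError(f"need at least 10 training samples, got {y.size}")
    if y.min() == y.max():
        raise ValueError("training data contains a single class")
    root = _grow(X, y, 0, depth_limit)
    return DecisionTreeModel(
        root=root,
        metadata={"seed": seed, "depth_limit": depth_limit, "n_samples": int(y.size)},
    )


def predict(model: DecisionTreeModel, features: CometFeatures) -> str:
    """Classify one candidate region as ``tailed_comet`` or ``head_only``."""
    x = features.as_array()
    node = model.root
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node.klass


_DEFAULT_MODEL_SEED = 20231117
_default_model: DecisionTreeModel | None = None


def train_default_model(n: int = 300, seed: int = _DEFAULT_MODEL_SEED) -> DecisionTreeModel:
    """Train the packaged default model on the synthetic generator."""
    from .synthetic import generate_labeled_feature_set

    feats, labels = generate_labeled_feature_set(n, seed=seed)
    return train_tree(feats, labels, depth_limit=3, seed=seed)


def default_model() -> DecisionTreeModel:
    """The lazily trained, cached default tailed/head-only classifier."""
    global _default_model
    if _default_model is None:
        _default_model = train_default_model()
    return _default_model
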