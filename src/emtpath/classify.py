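"""Tile classifiers: splitting, slide-wise folds, class balancing, training.

Two classifiers drive the imaging arm: a 3-class tumor detector
(necrosis / stroma / tumor) trained on a stratified 7:1.5:1.5 split, and a
2-class Epi/Mes detector trained with slide-wise k-fold cross-validation so
no slide's tiles leak between training and validation.  Class imbalance is
handled the way the study design prescribes: keep every Epi slide,
downsample Mes slides to a 1:2 Epi:Mes ratio, then sample at most 600 tumor
tiles per Epi slide and 300 per Mes slide.

Training follows the transfer-learning contract: a frozen convolutional
backbone with a global-average-pooling (GAP) output, and only the final
softmax layer fit — by stochastic gradient descent at learning rate 0.01.
The GAP + linear head makes class activation maps well-defined.  The
default test backbone ("small-cnn") is a fixed, seeded 3-block convolutional
feature extractor implemented on numpy; an "inception-v3-pretrained"
backbone can be used where torch/torchvision are installed.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import roc_auc_score

__all__ = [
    "SplitSpec",
    "FoldAssignment",
    "BalancingConfig",
    "TrainingConfig",
    "TileDataset",
    "TileClassifier",
    "Metrics",
    "SmallCNNBackbone",
    "get_backbone",
    "split_three_way",
    "make_slidewise_folds",
    "balance_training_tiles",
    "train_tile_classifier",
    "fit_softmax_head",
    "evaluate",
]


# ---------------------------------------------------------------------------
# configs / containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {sum(self.ratios)}")
        if any(r < 0 for r in self.ratios):
            raise ValueError("split ratios must be nonnegative")


@dataclass
class FoldAssignment:
    k: int
    fold_of: dict  # slide id -> fold index

    def folds(self):
        out = [[] for _ in range(self.k)]
        for s, f in self.fold_of.items():
            out[f].append(s)
        return out


@dataclass(frozen=True)
class BalancingConfig:
    mes_slides_per_epi_slide: int = 2       # the 1:2 Epi:Mes slide ratio
    tiles_per_epi_slide: int = 600
    tiles_per_mes_slide: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tiles_per_epi_slide <= 0 or self.tiles_per_mes_slide <= 0:
            raise ValueError("tile caps must be > 0")
        if self.mes_slides_per_epi_slide <= 0:
            raise ValueError("slide ratio must be > 0")


@dataclass(frozen=True)
class TrainingConfig:
    backbone: str = "small-cnn"
    learning_rate: float = 0.01
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be > 0")


@dataclass
class TileDataset:
    """References to training tiles with labels and slide membership."""

    tiles: list            # tile references (arrays or opaque ids)
    labels: list           # class label per tile
    slide_of: list         # slide id per tile

    def __post_init__(self) -> None:
        if not (len(self.tiles) == len(self.labels) == len(self.slide_of)):
            raise ValueError("tiles, labels and slide_of must align")


@dataclass
class Metrics:
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    f1: float
    per_class: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "auc": self.auc,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "f1": self.f1, "per_class": self.per_class}


# ---------------------------------------------------------------------------
# splitting / folds / balancing
# ---------------------------------------------------------------------------

def _apportion(n: int, ratios) -> list[int]:
    """Largest-remainder apportionment of n items into len(ratios) shares."""
    raw = np.array(ratios) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i]] += 1
    return base.tolist()


def split_three_way(items, labels, spec: SplitSpec | None = None):
    """Stratified train/validation/test split at the configured ratios.

    Stratification first, largest-remainder apportionment within each class;
    returns three disjoint lists of items whose union is the input.
    """
    spec = spec or SplitSpec()
    items = list(items)
    labels = list(labels)
    if len(items) != len(labels):
        raise ValueError("items and labels must align")
    if len(items) < 20:
        raise ValueError("need at least 20 items to split")
    rng = np.random.default_rng(spec.seed)
    splits = ([], [], [])
    for cls in sorted(set(map(str, labels))):
        idx = [i for i, lab in enumerate(labels) if str(lab) == cls]
        idx = [idx[j] for j in rng.permutation(len(idx))]
        counts = _apportion(len(idx), spec.ratios)
        start = 0
        for part, cnt in zip(splits, counts):
            part.extend(items[i] for i in idx[start:start + cnt])
            start += cnt
    return splits


def make_slidewise_folds(slide_labels: dict, k: int = 6,
                         seed: int = 0) -> FoldAssignment:
    """Stratified slide-level k-fold partition.

    Every tile of a slide inherits the slide's fold, preventing leakage; per
    class, fold sizes differ by at most one slide.
    """
    by_class = {}
    for slide, lab in slide_labels.items():
        by_class.setdefault(lab, []).append(slide)
    for lab, slides in by_class.items():
        if len(slides) < k:
            raise ValueError(f"class {lab!r} has {len(slides)} slides; needs >= {k}")
    rng = np.random.default_rng(seed)
    fold_of = {}
    for lab in sorted(by_class):
        slides = sorted(by_class[lab])
        perm = rng.permutation(len(slides))
        for pos, j in enumerate(perm):
            fold_of[slides[j]] = pos % k
    return FoldAssignment(k=k, fold_of=fold_of)


def balance_training_tiles(slide_labels: dict, tiles_by_slide: dict,
                           config: BalancingConfig | None = None) -> TileDataset:
    """Slide- and tile-level balancing of the Epi/Mes training pool.

    All Epi slides are kept; Mes slides are downsampled (without
    replacement) to twice the Epi slide count when enough exist; per slide
    at most 600 (Epi) / 300 (Mes) tumor tiles are sampled without
    replacement.  Slides contributing zero tumor tiles are skipped with a
    warning.
    """
    from .signature import EPI, MES

    config = config or BalancingConfig()
    epi_slides = sorted(s for s, lab in slide_labels.items() if lab == EPI)
    mes_slides = sorted(s for s, lab in slide_labels.items() if lab == MES)
    if not epi_slides:
        raise ValueError("no Epi slides in the training folds")
    rng = np.random.default_rng(config.seed)
    n_mes_keep = min(len(mes_slides),
                     config.mes_slides_per_epi_slide * len(epi_slides))
    kept_mes = [mes_slides[i] for i in
                rng.choice(len(mes_slides), size=n_mes_keep, replace=False)]

    tiles, labels, slide_of = [], [], []
    for slide, cap, lab in (
            [(s, config.tiles_per_epi_slide, EPI) for s in epi_slides]
            + [(s, config.tiles_per_mes_slide, MES) for s in sorted(kept_mes)]):
        pool = list(tiles_by_slide.get(slide, []))
        if not pool:
            warnings.warn(f"slide {slide!r} has no tumor tiles; skipped",
                          stacklevel=2)
            continue
        n_take = min(cap, len(pool))
        take = rng.choice(len(pool), size=n_take, replace=False)
        for i in take:
            tiles.append(pool[i])
            labels.append(lab)
            slide_of.append(slide)
    return TileDataset(tiles=tiles, labels=labels, slide_of=slide_of)


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

def _conv2d_same(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """3x3 same-padding convolution: x (N,H,W,C) with weights (K,3,3,C)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    windows = sliding_window_view(xp, (3, 3), axis=(1, 2))  # N,H,W,C,3,3
    return np.einsum("nhwcij,kijc->nhwk", windows, weights, optimize=True)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


class SmallCNNBackbone:
    """Frozen 3-block convolutional feature extractor for CPU-scale tests.

    Input tiles are area-averaged to 64x64, shifted to [-0.5, 0.5], and
    passed through three fixed (seeded He-initialized) 3x3 conv + ReLU +
    2x2 max-pool blocks, ending in 8x8 feature maps whose global average
    pooling is the feature vector.  The weights never change — only the
    downstream softmax head is trainable — so the transfer-learning
    contract (frozen backbone, retrained final layer) holds by construction.
    """

    name = "small-cnn"
    input_size = 64

    def __init__(self, n_filters=(8, 16, 32), seed: int = 12345):
        rng = np.random.default_rng(seed)
        self.weights = []
        c_in = 3
        for k in n_filters:
            w = rng.normal(0.0, np.sqrt(2.0 / (9 * c_in)),
                           size=(k, 3, 3, c_in)).astype(np.float32)
            self.weights.append(w)
            c_in = k
        self.n_features = n_filters[-1]

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[None]
        n, h, w, _ = x.shape
        x = np.ascontiguousarray(x)
        fy, fx = h // self.input_size, w // self.input_size
        x = x.astype(np.float32) / 255.0
        if fy > 1 or fx > 1:
            x = x[:, :fy * self.input_size, :fx * self.input_size]
            x = x.reshape(n, self.input_size, fy, self.input_size, fx, 3).mean((2, 4))
        return x - 0.5

    def feature_maps(self, images: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Final conv feature maps (N, 8, 8, K) after ReLU."""
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        outs = []
        for i in range(0, images.shape[0], chunk):
            h = self._prepare(images[i:i + chunk])  # chunked: bounds memory
            for w in self.weights:
                h = np.maximum(_conv2d_same(h, w), 0.0)
                h = _maxpool2(h)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def features(self, images: np.ndarray) -> np.ndarray:
        """Global-average-pooled features (N, K)."""
        return self.feature_maps(images).mean(axis=(1, 2))

    def checksum(self) -> str:
        md = hashlib.sha256()
        for w in self.weights:
            md.update(w.tobytes())
        return md.hexdigest()


def get_backbone(name: str, seed: int = 12345):
    if name == "small-cnn":
        return SmallCNNBackbone(seed=seed)
    if name == "inception-v3-pretrained":
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the inception-v3-pretrained backbone requires torch and "
                "torchvision; install them or use backbone='small-cnn'"
            ) from exc
        raise NotImplementedError(
            "inception-v3 wiring requires a torch runtime; use 'small-cnn'")
    raise ValueError(f"unknown backbone {name!r}")


# ---------------------------------------------------------------------------
# head training
# ---------------------------------------------------------------------------

def fit_softmax_head(features: np.ndarray, labels, config: TrainingConfig):
    """Fit a multinomial softmax layer by minibatch SGD.

    Features are standardized with training-set statistics during
    optimization; the standardization is folded back into the returned
    (weights, bias) so the head is exactly linear over raw GAP features —
    the form class activation mapping requires.  Returns
    (classes, weights (K, C), bias (C,), loss curve).
    """
    x = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.array(sorted(set(map(str, labels))))
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    y = np.searchsorted(classes, labels.astype(str))

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd

    rng = np.random.default_rng(config.seed)
    n, k = xs.shape
    c = classes.size
    w = rng.normal(0.0, 0.01, size=(k, c))
    b = np.zeros(c)
    onehot = np.eye(c)[y]
    curve = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = xs[idx] @ w + b
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            grad = (probs - onehot[idx]) / idx.size
            w -= config.learning_rate * (xs[idx].T @ grad)
            b -= config.learning_rate * grad.sum(axis=0)
        logits = xs @ w + b
        logits -= logits.max(axis=1, keepdims=True)
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        curve.append(float(-logp[np.arange(n), y].mean()))

    w_raw = w / sd[:, None]
    b_raw = b - (mu / sd) @ w
    return classes, w_raw, b_raw, curve


@dataclass
class TileClassifier:
    """Frozen backbone + linear softmax head over GAP features."""

    backbone: SmallCNNBackbone
    classes: np.ndarray
    weights: np.ndarray       # (K, C), applied to raw GAP features
    bias: np.ndarray          # (C,)
    training_curve: list = field(default_factory=list)

    def predict_proba_features(self, features: np.ndarray) -> np.ndarray:
        logits = np.asarray(features) @ self.weights + self.bias
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba_features(self.backbone.features(images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.classes[self.predict_proba(images).argmax(axis=1)]

    def class_index(self, cls) -> int:
        idx = np.where(self.classes == str(cls))[0]
        if idx.size == 0:
            raise KeyError(f"unknown class {cls!r}")
        return int(idx[0])

    def save(self, path) -> None:
        np.savez(path, classes=self.classes, weights=self.weights,
                 bias=self.bias, backbone=self.backbone.name)

    @classmethod
    def load(cls, path, backbone: SmallCNNBackbone | None = None):
        d = np.load(path, allow_pickle=False)
        bb = backbone or get_backbone(str(d["backbone"]))
        return cls(backbone=bb, classes=d["classes"].astype(str),
                   weights=d["weights"], bias=d["bias"])


def train_tile_classifier(images, labels, config: TrainingConfig | None = None,
                          backbone: SmallCNNBackbone | None = None,
                          features: np.ndarray | None = None) -> TileClassifier:
    """Train the final softmax layer on top of a frozen backbone.

    ``features`` may carry precomputed GAP features for the same images to
    avoid re-extraction in cross-validation loops.
    """
    config = config or TrainingConfig()
    backbone = backbone or get_backbone(config.backbone)
    if features is None:
        features = backbone.features(np.asarray(images))
    classes, w, b, curve = fit_softmax_head(features, labels, config)
    return TileClassifier(backbone=backbone, classes=classes, weights=w, bias=b,
                          training_curve=curve)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(labels, probs, classes) -> Metrics:
    """Accuracy, rank-based ROC-AUC, sensitivity, specificity, F1.

    Binary tasks use the second class of ``classes`` as positive; multiclass
    metrics are one-vs-rest macro averages.
    """
    labels = np.asarray(labels).astype(str)
    probs = np.asarray(probs, dtype=float)
    classes = np.asarray(classes).astype(str)
    if probs.ndim == 1:
        probs = np.column_stack([1.0 - probs, probs])
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    y_idx = np.searchsorted(classes, labels)
    pred_idx = probs.argmax(axis=1)
    accuracy = float((pred_idx == y_idx).mean())

    per_class = {}
    for j, cls in enumerate(classes):
        pos = y_idx == j
        if pos.all() or not pos.any():
            continue
        auc = float(roc_auc_score(pos, probs[:, j]))
        tp = int(((pred_idx == j) & pos).sum())
        fn = int(((pred_idx != j) & pos).sum())
        fp = int(((pred_idx == j) & ~pos).sum())
        tn = int(((pred_idx != j) & ~pos).sum())
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        per_class[str(cls)] = {"auc": auc, "sensitivity": sens,
                               "specificity": spec, "f1": f1}

    if classes.size == 2:
        head = per_class[str(classes[1])]
        return Metrics(accuracy=accuracy, auc=head["auc"],
                       sensitivity=head["sensitivity"],
                       specificity=head["specificity"], f1=head["f1"],
                       per_class=per_class)
    macro = {k: float(np.mean([v[k] for v in per_class.values()]))
             for k in ("auc", "sensitivity", "specificity", "f1")}
    return Metrics(accuracy=accuracy, auc=macro["auc"],
                   sensitivity=macro["sensitivity"],
                   specificity=macro["specificity"], f1=macro["f1"],
                   per_class=per_class)
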