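"""End-to-end synthetic experiment: slides -> tiles -> tumor detection ->
slide-wise cross-validated EMT classification -> slide calls.

This mirrors the full imaging pipeline at desk scale: synthetic mini-slides
are tiled and background-filtered, a 3-class tumor detector (trained on a
stratified 7:1.5:1.5 split of rendered necrosis/stroma/tumor tiles) picks
out tumor tiles, and an Epi/Mes classifier is trained with slide-wise
k-fold cross-validation using the 1:2 slide downsampling and 600/300
per-slide tile caps, with mean-probability slide aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify, preprocess
from .classify import (BalancingConfig, SplitSpec, TrainingConfig, evaluate,
                       fit_softmax_head, get_backbone, make_slidewise_folds,
                       split_three_way, train_tile_classifier)
from .inference import aggregate_slide
from .signature import EPI, MES
from .synthetic import SlideSpec, generate_slide, render_tile, _rng

__all__ = ["ExperimentResult", "run_subtype_experiment", "train_tumor_detector"]


@dataclass
class ExperimentResult:
    tumor_detector_metrics: dict
    fold_slide_auc: list
    mean_slide_auc: float
    pooled_slide_auc: float
    fold_tile_auc: list
    mean_tile_auc: float
    slide_calls: list = field(default_factory=list)
    fold_of: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "tumor_detector": self.tumor_detector_metrics,
            "fold_slide_auc": self.fold_slide_auc,
            "mean_slide_auc": self.mean_slide_auc,
            "pooled_slide_auc": self.pooled_slide_auc,
            "fold_tile_auc": self.fold_tile_auc,
            "mean_tile_auc": self.mean_tile_auc,
        }


def train_tumor_detector(spec: SlideSpec, backbone, n_per_class: int = 1000,
                         seed: int = 0, epochs: int = 5):
    """Render labeled necrosis/stroma/tumor tiles, split 7:1.5:1.5
    stratified, and retrain the softmax head of the frozen backbone."""
    rng = _rng(seed, "tumor-detector")
    labels, feat_chunks, batch = [], [], []
    for cls in ("necrosis", "stroma", "tumor"):
        for i in range(n_per_class):
            subtype = None
            if cls == "tumor":
                subtype = MES if i % 2 == 0 else EPI
            batch.append(render_tile(cls, subtype, spec,
                                     int(rng.integers(0, 2**31 - 1))))
            labels.append(cls)
            if len(batch) == 256:  # stream tiles; never hold the full stack
                feat_chunks.append(backbone.features(np.stack(batch)))
                batch = []
    if batch:
        feat_chunks.append(backbone.features(np.stack(batch)))
    feats = np.concatenate(feat_chunks, axis=0)
    idx_split = split_three_way(list(range(len(labels))), labels,
                                SplitSpec(seed=seed))
    tr, va, te = idx_split
    cfg = TrainingConfig(epochs=epochs, seed=seed)
    clf = train_tile_classifier(None, [labels[i] for i in tr], cfg,
                                backbone=backbone, features=feats[tr])
    test_probs = clf.predict_proba_features(feats[te])
    metrics = evaluate([labels[i] for i in te], test_probs, clf.classes)
    return clf, metrics


def run_subtype_experiment(n_epi: int = 20, n_mes: int = 40, k: int = 3,
                           grid_shape: tuple[int, int] = (14, 14),
                           seed: int = 0, epochs: int = 5,
                           detector_tiles_per_class: int = 1000,
                           normalize_stains: bool = False) -> ExperimentResult:
    """Run the scaled-down EMT-subtype experiment on synthetic slides.

    Generates ``n_epi`` epithelial and ``n_mes`` mesenchymal mini-slides,
    detects tumor tiles with the 3-class detector, and evaluates Epi/Mes
    classification with slide-wise ``k``-fold cross-validation; the slide
    call is the mean tumor-tile Mes probability.  Returns per-fold and
    pooled slide-level AUCs.
    """
    backbone = get_backbone("small-cnn")
    base_spec = SlideSpec(seed=seed, grid_shape=grid_shape)
    detector, det_metrics = train_tumor_detector(
        base_spec, backbone, n_per_class=detector_tiles_per_class,
        seed=seed, epochs=epochs)

    reference = preprocess.default_reference_profile()
    slide_labels: dict[str, str] = {}
    slide_features: dict[str, np.ndarray] = {}

    names = [f"epi{i:03d}" for i in range(n_epi)] + \
            [f"mes{i:03d}" for i in range(n_mes)]
    subtypes = [EPI] * n_epi + [MES] * n_mes
    for name, subtype in zip(names, subtypes):
        spec = SlideSpec(subtype=subtype, grid_shape=grid_shape,
                         seed=int(_rng(seed, "slide-seed", name).integers(0, 2**31 - 1)))
        slide = generate_slide(spec, slide_id=name)
        tiles = preprocess.tile_image(slide.image, slide_id=name)
        kept, _ = preprocess.filter_tiles(tiles)
        if normalize_stains and kept:
            pool = preprocess.pool_tile_pixels(kept, seed=spec.seed)
            profile = preprocess.estimate_stain_profile(pool)
            kept = [preprocess.normalize_tile(t, profile, reference) for t in kept]
        if not kept:
            continue
        feats = backbone.features(np.stack([t.pixels for t in kept]))
        pred = detector.classes[
            detector.predict_proba_features(feats).argmax(axis=1)]
        tumor_feats = feats[pred == "tumor"]
        if tumor_feats.shape[0] == 0:
            continue
        slide_labels[name] = subtype
        slide_features[name] = tumor_feats

    folds = make_slidewise_folds(slide_labels, k=k, seed=seed)
    fold_slide_auc, fold_tile_auc, slide_calls = [], [], []
    pooled_scores, pooled_labels = [], []
    for fold in range(k):
        train_slides = {s: lab for s, lab in slide_labels.items()
                        if folds.fold_of[s] != fold}
        val_slides = [s for s in slide_labels if folds.fold_of[s] == fold]
        tiles_by_slide = {s: list(range(slide_features[s].shape[0]))
                          for s in train_slides}
        ds = classify.balance_training_tiles(train_slides, tiles_by_slide,
                                             BalancingConfig(seed=seed + fold))
        feats = np.stack([slide_features[s][i]
                          for s, i in zip(ds.slide_of, ds.tiles)])
        classes, w, b, _ = fit_softmax_head(
            feats, ds.labels, TrainingConfig(epochs=epochs, seed=seed + fold))
        head = classify.TileClassifier(backbone=backbone, classes=classes,
                                       weights=w, bias=b)
        mes_col = head.class_index(MES)

        val_tile_probs, val_tile_labels = [], []
        for s in val_slides:
            probs = head.predict_proba_features(slide_features[s])[:, mes_col]
            pred = aggregate_slide(probs, slide_id=s)
            slide_calls.append({"slide_id": s, "truth": slide_labels[s],
                                "ai_score": pred.ai_score, "call": pred.call,
                                "fold": fold})
            pooled_scores.append(pred.ai_score)
            pooled_labels.append(slide_labels[s])
            val_tile_probs.append(probs)
            val_tile_labels.extend([slide_labels[s]] * probs.size)
        scores = [c["ai_score"] for c in slide_calls if c["fold"] == fold]
        labs = [c["truth"] for c in slide_calls if c["fold"] == fold]
        fold_slide_auc.append(
            evaluate(labs, np.asarray(scores), [EPI, MES]).auc)
        fold_tile_auc.append(
            evaluate(val_tile_labels, np.concatenate(val_tile_probs),
                     [EPI, MES]).auc)

    pooled_auc = evaluate(pooled_labels, np.asarray(pooled_scores),
                          [EPI, MES]).auc
    return ExperimentResult(
        tumor_detector_metrics=det_metrics.as_dict(),
        fold_slide_auc=fold_slide_auc,
        mean_slide_auc=float(np.mean(fold_slide_auc)),
        pooled_slide_auc=pooled_auc,
        fold_tile_auc=fold_tile_auc,
        mean_tile_auc=float(np.mean(fold_tile_auc)),
        slide_calls=slide_calls,
        fold_of=dict(folds.fold_of),
    )
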