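"""End-to-end pipelines tying the modules together.

``build_palette_from_dataset`` runs the two-stage palette learning on a
labeled tile collection; ``extract_features`` maps tiles to texture
records; ``planted_recovery`` is the full train-on-one-seed /
evaluate-on-a-fresh-seed harness used to validate that the pipeline
(palette -> CCM features -> multilabel MLP -> clinical rule) recovers the
structure planted by the synthetic generator.
"""

from __future__ import annotations

import numpy as np

from . import classify, evaluate, synthdata, texture
from .colorspace import ViewingConditions
from .palette import (PATTERN_CLASSES, Palette, build_master_palette,
                      cluster_pattern_colors)
from .synthdata import SyntheticDataset

__all__ = [
    "build_palette_from_dataset",
    "extract_features",
    "labels_to_detections",
    "binary_truth",
    "planted_recovery",
]


def build_palette_from_dataset(
    ds: SyntheticDataset,
    k_per_pattern: int = 18,
    target_n: int = 20,
    space: str = "cam16ucs",
    seed: int = 0,
    *,
    max_pixels_per_image: int = 50_000,
    vc: ViewingConditions | None = None,
) -> Palette:
    """Two-stage palette learning from a labeled tile collection: pooled
    per-pattern K-means (k centroids each), then threshold merging to
    exactly ``target_n`` master colors."""
    from . import colorspace as cs

    vc = vc or ViewingConditions()
    rng = np.random.default_rng(seed)
    per_pattern = {}
    for ki, pattern in enumerate(PATTERN_CLASSES):
        rows = np.flatnonzero(ds.labels[:, ki] == 1)
        pools = []
        for r in rows:
            px = np.asarray(ds.images[r]).reshape(-1, 3)
            if px.shape[0] > max_pixels_per_image:
                sel = rng.choice(px.shape[0], max_pixels_per_image, replace=False)
                px = px[sel]
            pools.append(px)
        if not pools:
            continue
        work = cs.srgb_to_working(np.concatenate(pools), space, vc)
        per_pattern[pattern] = cluster_pattern_colors(
            work, k=k_per_pattern, seed=seed + ki, source=pattern,
            space=space, vc=vc,
        )
    return build_master_palette(per_pattern, target_n, space=space, vc=vc)


def extract_features(
    images, pal: Palette, mode: str = "ccm",
    spec: texture.OffsetSpec | None = None,
) -> np.ndarray:
    """(N, 7) matrix of texture feature records in FEATURE_NAMES order."""
    recs = [texture.image_features(img, pal, mode=mode, spec=spec) for img in images]
    return np.array([[r[k] for k in texture.FEATURE_NAMES] for r in recs])


def labels_to_detections(label_row) -> dict:
    return {p: bool(label_row[i]) for i, p in enumerate(PATTERN_CLASSES)}


def binary_truth(labels: np.ndarray, mode: str = "strict") -> np.ndarray:
    """Ground-truth BCC / non-BCC labels implied by the clinical rule."""
    return np.array(
        [classify.bcc_rule(labels_to_detections(row), mode) == "BCC" for row in labels]
    )


def planted_recovery(
    seed: int = 0,
    *,
    n_train_per_pattern: int = 50,
    n_test_per_pattern: int = 25,
    tile: int = 64,
    space: str = "cam16ucs",
    rule_mode: str = "strict",
    max_pixels_per_image: int = 1500,
) -> dict:
    """Train on one synthetic seed, evaluate on a fresh seed.

    Returns the multilabel report, the tuned thresholds, and the binary
    BCC metrics under the clinical rule.  Seeds derived from ``seed`` keep
    the train and test collections disjoint in distribution draws.
    """
    size = (tile, tile)
    train = synthdata.make_dataset(n_train_per_pattern, size, seed=seed)
    test = synthdata.make_dataset(n_test_per_pattern, size, seed=seed + 104729)

    pal = build_palette_from_dataset(
        train, space=space, seed=seed, max_pixels_per_image=max_pixels_per_image
    )
    X_train = extract_features(train.images, pal)
    X_test = extract_features(test.images, pal)

    model = classify.train_feature_classifier(X_train, train.labels, seed=seed)
    P_train = model.forward(X_train)
    thresholds = classify.select_thresholds(P_train, train.labels)
    P_test = model.forward(X_test)

    report = evaluate.multilabel_report(P_test, test.labels, thresholds)

    det = P_test >= np.array([thresholds[p] for p in PATTERN_CLASSES])
    pred_bcc = np.array(
        [classify.bcc_rule(labels_to_detections(row), rule_mode) == "BCC" for row in det]
    )
    true_bcc = binary_truth(test.labels, rule_mode)
    binary = evaluate.metrics_from_counts(evaluate.confusion(true_bcc, pred_bcc))
    return {
        "palette": pal,
        "model": model,
        "thresholds": thresholds,
        "multilabel": report,
        "binary": binary,
        "n_train": len(train),
        "n_test": len(test),
    }
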