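"""Multilabel detection of the seven dermoscopic patterns and the clinical
BCC rule.

A small feed-forward network maps a texture feature record to seven
independent sigmoid outputs, one per pattern (an image may show several
patterns at once, so the outputs are not a distribution).  Training
minimizes binary cross-entropy; rare patterns can be up-weighted through
per-pattern positive weights.  Thresholded detections then feed the
clinical rule: a lesion is called BCC when at least one of the six
positive criteria is present and (in strict mode) the pigment network —
the sole negative criterion — is absent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .palette import PATTERN_CLASSES, POSITIVE_PATTERNS, Palette
from .texture import FEATURE_NAMES, OffsetSpec, image_features

__all__ = [
    "FeatureClassifierModel",
    "train_feature_classifier",
    "predict_patterns",
    "apply_thresholds",
    "select_thresholds",
    "bcc_rule",
    "diagnose",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = {p: 0.5 for p in PATTERN_CLASSES}


class ClassifierError(ValueError):
    pass


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class FeatureClassifierModel:
    """Weights, standardization constants and training metadata of the
    multilabel pattern detector."""

    layer_sizes: tuple  # e.g. (7, 32, 16, 7)
    weights: list  # list of (in, out) arrays
    biases: list  # list of (out,) arrays
    feature_names: tuple
    mu: np.ndarray  # per-feature training mean
    scale: np.ndarray  # per-feature training std (floored)
    seed: int
    loss_curve: list = field(default_factory=list)

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = (np.asarray(X, dtype=float) - self.mu) / self.scale
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return _sigmoid(a @ self.weights[-1] + self.biases[-1])

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_names": list(self.feature_names),
            "mu": self.mu.tolist(),
            "scale": self.scale.tolist(),
            "seed": self.seed,
            "loss_curve": [float(v) for v in self.loss_curve],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "FeatureClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            layer_sizes=tuple(d["layer_sizes"]),
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            feature_names=tuple(d["feature_names"]),
            mu=np.asarray(d["mu"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            seed=int(d["seed"]),
            loss_curve=list(d["loss_curve"]),
        )


def _as_matrix(features, feature_names=None):
    if isinstance(features, np.ndarray):
        if feature_names is None:
            # bare matrices in the canonical arity are texture records
            feature_names = (FEATURE_NAMES if features.shape[-1] == len(FEATURE_NAMES)
                             else [f"f{i}" for i in range(features.shape[-1])])
        return np.asarray(features, dtype=float), tuple(feature_names)
    # sequence of dict records
    names = tuple(feature_names or FEATURE_NAMES)
    X = np.array([[rec[k] for k in names] for rec in features], dtype=float)
    return X, names


def train_feature_classifier(
    features,
    labels,
    seed: int = 0,
    *,
    hidden: tuple = (32, 16),
    max_epochs: int = 500,
    batch_size: int = 32,
    lr: float = 5e-3,
    val_fraction: float = 0.15,
    patience: int = 40,
    pos_weight: bool = True,
    feature_names=None,
) -> FeatureClassifierModel:
    """Train the multilabel MLP.

    ``features``: (N, d) array or sequence of feature records;
    ``labels``: (N, 7) binary array in the fixed pattern order.
    Adam with minibatches, early stopping on a held-out validation BCE,
    fully deterministic for a given seed.  Patterns whose labels are
    constant in the training data trigger a warning but are trained.
    """
    X, names = _as_matrix(features, feature_names)
    Y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or Y.shape[1] != len(PATTERN_CLASSES):
        raise ClassifierError(
            f"expected (N, d) features and (N, {len(PATTERN_CLASSES)}) labels, "
            f"got {X.shape} and {Y.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ClassifierError("non-finite feature values")
    for k, pattern in enumerate(PATTERN_CLASSES):
        if Y[:, k].min() == Y[:, k].max():
            warnings.warn(
                f"pattern {pattern!r} is {'all-positive' if Y[0, k] else 'all-negative'} "
                "in the training labels; its output cannot be calibrated",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 4 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx = perm
    mu = X[tr_idx].mean(axis=0)
    scale = np.maximum(X[tr_idx].std(axis=0), 1e-8)
    Xs = (X - mu) / scale

    # per-pattern positive weights to counter class imbalance
    if pos_weight:
        pos = np.clip(Y[tr_idx].mean(axis=0), 1e-3, 1 - 1e-3)
        w_pos = np.clip((1 - pos) / pos, 1.0, 20.0)
    else:
        w_pos = np.ones(Y.shape[1])

    sizes = (X.shape[1], *hidden, Y.shape[1])
    Ws = [rng.normal(0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
          for i in range(len(sizes) - 1)]
    bs = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    mW = [np.zeros_like(w) for w in Ws]
    vW = [np.zeros_like(w) for w in Ws]
    mb = [np.zeros_like(b) for b in bs]
    vb = [np.zeros_like(b) for b in bs]
    b1, b2, eps = 0.9, 0.999, 1e-8

    def bce(P, Yb):
        P = np.clip(P, 1e-12, 1 - 1e-12)
        w = np.where(Yb > 0.5, w_pos, 1.0)
        return float(np.mean(-w * (Yb * np.log(P) + (1 - Yb) * np.log(1 - P))))

    def raw_forward(Xb):
        acts = [Xb]
        a = Xb
        for W, b in zip(Ws[:-1], bs[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        P = _sigmoid(a @ Ws[-1] + bs[-1])
        return acts, P

    best = (np.inf, None, 0)
    loss_curve = []
    step = 0
    for epoch in range(max_epochs):
        order = rng.permutation(tr_idx)
        for start in range(0, order.size, batch_size):
            idx = order[start: start + batch_size]
            Xb, Yb = Xs[idx], Y[idx]
            acts, P = raw_forward(Xb)
            w = np.where(Yb > 0.5, w_pos, 1.0)
            # d(BCE)/d(logit) for weighted sigmoid BCE
            delta = w * (P - Yb) / (Xb.shape[0] * Y.shape[1])
            grads_W, grads_b = [], []
            for li in range(len(Ws) - 1, -1, -1):
                grads_W.append(acts[li].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if li > 0:
                    delta = (delta @ Ws[li].T) * (acts[li] > 0)
            grads_W.reverse(); grads_b.reverse()
            step += 1
            for li in range(len(Ws)):
                for g, m, v, theta in (
                    (grads_W[li], mW[li], vW[li], Ws[li]),
                    (grads_b[li], mb[li], vb[li], bs[li]),
                ):
                    m *= b1; m += (1 - b1) * g
                    v *= b2; v += (1 - b2) * g * g
                    mhat = m / (1 - b1**step)
                    vhat = v / (1 - b2**step)
                    theta -= lr * mhat / (np.sqrt(vhat) + eps)
        monitor = val_idx if val_idx.size else tr_idx
        _, Pm = raw_forward(Xs[monitor])
        loss = bce(Pm, Y[monitor])
        loss_curve.append(loss)
        if loss < best[0] - 1e-6:
            best = (loss, ([w.copy() for w in Ws], [b.copy() for b in bs]), epoch)
        elif epoch - best[2] >= patience:
            break
    if best[1] is not None:
        Ws, bs = best[1]
    return FeatureClassifierModel(
        layer_sizes=sizes, weights=Ws, biases=bs, feature_names=names,
        mu=mu, scale=scale, seed=seed, loss_curve=loss_curve,
    )


def predict_patterns(model: FeatureClassifierModel, features) -> dict:
    """Per-pattern probabilities for one feature record (or dict)."""
    if isinstance(features, Mapping):
        x = np.array([features[k] for k in model.feature_names], dtype=float)
    else:
        x = np.asarray(features, dtype=float)
    if x.shape[-1] != model.layer_sizes[0]:
        raise ClassifierError(
            f"feature arity {x.shape[-1]} does not match model input "
            f"{model.layer_sizes[0]}"
        )
    p = model.forward(x[None, :])[0]
    return dict(zip(PATTERN_CLASSES, p.astype(float)))


def apply_thresholds(p: Mapping[str, float], t: Mapping[str, float] | None = None) -> dict:
    """Detections d[k] = (p[k] >= t[k]); a tie counts as detected."""
    t = t or DEFAULT_THRESHOLDS
    return {k: bool(p[k] >= t[k]) for k in PATTERN_CLASSES}


def select_thresholds(prob_table: np.ndarray, label_table: np.ndarray) -> dict:
    """Per-pattern thresholds maximizing Youden's J (sens + spec - 1) on a
    validation set; falls back to 0.5 when a pattern is single-class."""
    P = np.asarray(prob_table, dtype=float)
    Y = np.asarray(label_table) > 0.5
    out = {}
    for k, pattern in enumerate(PATTERN_CLASSES):
        y, s = Y[:, k], P[:, k]
        if y.all() or not y.any():
            out[pattern] = 0.5
            continue
        cand = np.unique(s)
        best_t, best_j = 0.5, -np.inf
        for t in cand:
            pred = s >= t
            sens = np.mean(pred[y])
            spec = np.mean(~pred[~y])
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, float(t)
        out[pattern] = best_t
    return out


def bcc_rule(d: Mapping[str, bool], mode: Literal["strict", "permissive"] = "strict") -> str:
    """Clinical rule mapping pattern detections to a diagnosis.

    strict: BCC iff at least one positive criterion is detected AND the
    pigment network is absent.  permissive: BCC iff at least one positive
    criterion is detected, regardless of pigment network.  With no
    detections at all the lesion is non-BCC in both modes.
    """
    missing = [k for k in PATTERN_CLASSES if k not in d]
    if missing:
        raise ClassifierError(f"detections missing pattern(s): {missing}")
    if mode not in ("strict", "permissive"):
        raise ClassifierError(f"unknown rule mode {mode!r}")
    any_positive = any(bool(d[k]) for k in POSITIVE_PATTERNS)
    if mode == "strict":
        return "BCC" if any_positive and not d["pigment_network"] else "nonBCC"
    return "BCC" if any_positive else "nonBCC"


def diagnose(
    image: np.ndarray,
    pal: Palette,
    model: FeatureClassifierModel,
    thresholds: Mapping[str, float] | None = None,
    mode: Literal["strict", "permissive"] = "strict",
    *,
    texture_mode: str = "ccm",
    spec: OffsetSpec | None = None,
) -> dict:
    """End-to-end explainable diagnosis of one sRGB image.

    Returns the diagnosis together with the per-pattern probabilities and
    thresholded detections that justify it.
    """
    rec = image_features(image, pal, mode=texture_mode, spec=spec)
    probs = predict_patterns(model, rec)
    det = apply_thresholds(probs, thresholds)
    return {
        "diagnosis": bcc_rule(det, mode),
        "rule_mode": mode,
        "detections": det,
        "probabilities": probs,
        "features": rec,
    }
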