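"""Two-stage grain/fiber shape classification of particle crops.

Stage one is a morphometric rule (``rough_classify``): fibers are far more
elongated than even the most irregular natural grains (mean aspect ratio
3.16 for natural sediment grains, so the fiber gate sits above that).  The
rule alone cannot fully separate the classes on real imagery, so stage two
is a small convolutional network trained on 100x100 particle crops with
mirror and 90-degree-rotation augmentation, emitting a label plus a
confidence percentage (the predicted-class probability x 100).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .measure import ShapeStats
from .nn import SmallCNN

__all__ = [
    "CLASS_ORDER",
    "Prediction",
    "ClassifierModel",
    "rough_classify",
    "extract_crop",
    "normalize_crop",
    "build_training_set",
    "train_classifier",
    "classify",
]

#: Fixed label encoding stored with every model file.
CLASS_ORDER = ("grain", "fiber")

CROP_SIZE = 100
FIBER_ASPECT_THRESHOLD = 4.0


@dataclass(frozen=True)
class Prediction:
    label: str
    confidence_pct: float   # predicted-class probability x 100, >= 50 for binary


def rough_classify(stats: ShapeStats,
                   aspect_threshold: float = FIBER_ASPECT_THRESHOLD) -> str:
    """Rule-based split: fiber if aspect >= threshold, or if the shape is
    both elongated (aspect >= 3) and extremely non-circular (circ < 0.2)."""
    if stats.aspect_ratio >= aspect_threshold:
        return "fiber"
    if stats.aspect_ratio >= 3.0 and stats.circularity < 0.2:
        return "fiber"
    return "grain"


def extract_crop(frame: np.ndarray, centroid: tuple[float, float],
                 feret_max_px: float, size: int = CROP_SIZE) -> np.ndarray:
    """Cut a ``size x size`` crop centred on the particle centroid.

    Particles larger than the crop are handled by cutting a larger square
    region around the centroid and downscaling it to fit, preserving
    aspect; out-of-frame parts are padded with the frame's median
    (background) intensity.
    """
    frame = np.asarray(frame)
    half = size // 2
    region = size
    if feret_max_px > size - 8:
        region = int(np.ceil(feret_max_px)) + 16
        half = region // 2
    cx, cy = int(round(centroid[0])), int(round(centroid[1]))
    bg = float(np.median(frame))
    out = np.full((region, region), bg, dtype=float)
    y0, y1 = cy - half, cy - half + region
    x0, x1 = cx - half, cx - half + region
    fy0, fy1 = max(0, y0), min(frame.shape[0], y1)
    fx0, fx1 = max(0, x0), min(frame.shape[1], x1)
    out[fy0 - y0:fy1 - y0, fx0 - x0:fx1 - x0] = frame[fy0:fy1, fx0:fx1]
    if region != size:
        out = resize(out, (size, size), anti_aliasing=True, preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def normalize_crop(crop: np.ndarray) -> np.ndarray:
    """Per-crop min-max normalisation to [0, 1]: staining brightness varies
    from particle to particle and must not carry class information."""
    crop = crop.astype(float)
    lo, hi = crop.min(), crop.max()
    if hi <= lo:
        return np.zeros_like(crop)
    return (crop - lo) / (hi - lo)


_ORIENTATIONS = [(k, m) for m in (False, True) for k in range(4)]


def _orient(img: np.ndarray, k: int, mirror: bool) -> np.ndarray:
    out = np.fliplr(img) if mirror else img
    return np.rot90(out, k)


def build_training_set(crops: np.ndarray, labels: np.ndarray,
                       n_per_class: int = 250,
                       augment: tuple[str, ...] = ("mirror", "rot90"),
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balanced, augmented training set.

    ``n_per_class`` crops are sampled per class without replacement, then
    each is expanded by the requested augmentations: horizontal mirror
    (x2) and the four 90-degree rotations (x4), i.e. 250 per class become
    2000 per class with both.  Deterministic under ``seed``.

    Raises ``ValueError`` naming the deficient class if a class has fewer
    than ``n_per_class`` crops.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rot_ks = range(4) if "rot90" in augment else (0,)
    mirrors = (False, True) if "mirror" in augment else (False,)
    xs, ys = [], []
    for cls_idx, cls in enumerate(CLASS_ORDER):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_per_class:
            raise ValueError(
                f"class '{cls}' has only {len(idx)} crops, need {n_per_class}")
        chosen = rng.choice(idx, size=n_per_class, replace=False)
        for i in chosen:
            for m in mirrors:
                for k in rot_ks:
                    xs.append(_orient(crops[i], k, m))
                    ys.append(cls_idx)
    return np.stack(xs), np.array(ys)


@dataclass
class ClassifierModel:
    """Trained CNN plus its training metadata; reloads bit-identically."""

    net: SmallCNN
    metadata: dict = field(default_factory=dict)
    class_order: tuple[str, ...] = CLASS_ORDER

    def save(self, path: str | Path) -> None:
        arrays = self.net.state_arrays()
        meta = dict(self.metadata, class_order=list(self.class_order),
                    input_size=self.net.input_size,
                    n_classes=self.net.n_classes)
        np.savez(path, _meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            net = SmallCNN(input_size=meta["input_size"],
                           n_classes=meta["n_classes"], seed=0)
            net.load_state_arrays({k: data[k] for k in data.files if k != "_meta"})
        class_order = tuple(meta.pop("class_order"))
        return cls(net=net, metadata=meta, class_order=class_order)


def _preprocess(crops: np.ndarray, input_size: int) -> np.ndarray:
    """Normalise each crop and resample to the network input size."""
    out = np.empty((len(crops), input_size, input_size))
    for i, c in enumerate(crops):
        norm = normalize_crop(c)
        if norm.shape != (input_size, input_size):
            norm = resize(norm, (input_size, input_size), anti_aliasing=True,
                          preserve_range=True)
        out[i] = norm
    return out


def train_classifier(training_set: tuple[np.ndarray, np.ndarray],
                     max_epochs: int = 200, seed: int = 0,
                     batch_size: int = 32, lr: float = 1e-3,
                     input_size: int = 48,
                     error_target: float = 0.005,
                     min_epochs: int = 5) -> ClassifierModel:
    """Train the CNN on an augmented crop set.

    Training runs for at most ``max_epochs`` passes with early stop once
    the mean training cross-entropy falls below ``error_target`` — the
    learning converges to a small residual error, and a loss this low also
    means the confidence of nearly every training prediction is >99%.  With
    the 8-fold mirror/rotation augmentation the loss target can be crossed
    within the first pass or two while held-out probability margins are
    still soft, so at least ``min_epochs`` passes are always run.  A model
    that never converges is still returned, flagged in its metadata.
    """
    x_raw, y = training_set
    if len(x_raw) == 0:
        raise ValueError("empty training set")
    counts = np.bincount(y, minlength=len(CLASS_ORDER))
    if counts.min() == 0 or counts.max() != counts.min():
        raise ValueError("training set must be balanced and cover both classes")

    x = _preprocess(x_raw, input_size)
    net = SmallCNN(input_size=input_size, n_classes=len(CLASS_ORDER), seed=seed)
    rng = np.random.default_rng(seed + 1)
    n = len(x)
    epochs_run = 0
    final_error = 1.0
    converged = False
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            net.loss_and_grads(x[idx], y[idx])
            net.adam_step(lr=lr)
        epochs_run = epoch + 1
        losses = []
        for i in range(0, n, 512):
            probs = net.predict_proba(x[i:i + 512])
            losses.append(-np.log(probs[np.arange(len(probs)),
                                        y[i:i + 512]] + 1e-12))
        final_error = float(np.concatenate(losses).mean())
        if final_error < error_target and epochs_run >= min_epochs:
            converged = True
            break

    model = ClassifierModel(net=net, metadata=dict(
        n_train=int(n), n_per_class=int(counts[0]), epochs=epochs_run,
        max_epochs=max_epochs, seed=seed, lr=lr, batch_size=batch_size,
        final_training_loss=final_error, converged=converged,
        augmentation="as provided in training_set"))
    if not converged:
        import warnings
        warnings.warn(f"training did not reach error < {error_target} after "
                      f"{max_epochs} epochs (final error {final_error:.4f})")
    return model


def classify(model: ClassifierModel, crop: np.ndarray) -> Prediction:
    """Predict grain/fiber for one crop (or a batch via ``classify_batch``)."""
    return classify_batch(model, crop[None])[0]


def classify_batch(model: ClassifierModel, crops: np.ndarray) -> list[Prediction]:
    x = _preprocess(np.asarray(crops), model.net.input_size)
    probs = model.net.predict_proba(x)
    out = []
    for p in probs:
        k = int(p.argmax())
        out.append(Prediction(label=model.class_order[k],
                              confidence_pct=float(100.0 * p[k])))
    return out
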