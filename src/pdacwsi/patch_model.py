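"""Patch-level two-class CNN classifier.

Architecture follows the classification head used throughout the pipeline:
a convolutional backbone, a global average pooling layer, a fully connected
layer of 1,024 neurons and a 2-way softmax. Training protocol defaults:
Adam, learning rate 0.001, categorical cross-entropy, 100 epochs, batch
size 8, random weight initialisation, and the checkpoint with the highest
validation accuracy (earliest epoch on ties) is kept as the final model.

Backbones are presets: ``small_cnn`` is a 4-conv network sized for
desk-scale experiments on 256 px inputs; ``large_cnn`` is a deeper
full-run preset. Inputs are RGB uint8 patches, normalised per channel to
[-1, 1] and resized to the backbone's native input size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import nn
from .tiling import CARCINOMA, NORMAL, PatchRecord, SplitManifest

CLASS_NAMES = (NORMAL, CARCINOMA)  # class ids 0, 1


@dataclass
class TrainingConfig:
    backbone: str = "small_cnn"
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0
    input_size: int | None = None  # None -> backbone native size
    checkpoint_metric: str = "val_accuracy"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class PatchPrediction:
    slide_id: str
    x: int
    y: int
    p_normal: float
    p_tumor: float


def _backbone_small(rng) -> tuple[list, int, int]:
    layers = []
    channels = [3, 8, 16, 32, 64]
    pools = [4, 4, 2, 2]
    for (c_in, c_out), pool in zip(zip(channels, channels[1:]), pools):
        layers += [nn.Conv2D(c_in, c_out, rng), nn.ReLU(), nn.MaxPool(pool)]
    return layers, channels[-1], 256


def _backbone_large(rng) -> tuple[list, int, int]:
    layers = []
    channels = [3, 32, 64, 128, 256, 512]
    for c_in, c_out in zip(channels, channels[1:]):
        layers += [nn.Conv2D(c_in, c_out, rng), nn.ReLU(), nn.MaxPool(2)]
    return layers, channels[-1], 256


_BACKBONES = {"small_cnn": _backbone_small, "large_cnn": _backbone_large}


@dataclass
class PatchClassifier:
    """Backbone + GAP + FC(1024) + softmax head, with bookkeeping."""

    net: nn.Sequential
    config: TrainingConfig
    input_size: int
    conv_indices: list[int]
    best_epoch: int | None = None
    best_val_accuracy: float | None = None
    log: pd.DataFrame | None = field(default=None, repr=False)

    def head_parameter_count(self) -> int:
        """Parameters in GAP + FC-1024 + softmax head (GAP itself has none)."""
        gap = max(i for i, l in enumerate(self.net.layers)
                  if isinstance(l, nn.GlobalAvgPool))
        return sum(p.size for l in self.net.layers[gap:] for p in l.params.values())


def build_classifier(config: TrainingConfig) -> PatchClassifier:
    """Assemble the network; weights are randomly initialised from
    config.seed, so two builds with the same seed are identical."""
    if config.backbone not in _BACKBONES:
        raise ValueError(f"unknown backbone {config.backbone!r}; "
                         f"choose from {sorted(_BACKBONES)}")
    rng = np.random.Generator(np.random.PCG64(config.seed))
    backbone, feat, native = _BACKBONES[config.backbone](rng)
    head = [nn.GlobalAvgPool(),
            nn.Dense(feat, 1024, rng), nn.ReLU(),
            nn.Dense(1024, 2, rng)]
    net = nn.Sequential(backbone + head)
    conv_indices = [i for i, l in enumerate(net.layers) if isinstance(l, nn.Conv2D)]
    return PatchClassifier(net=net, config=config,
                           input_size=config.input_size or native,
                           conv_indices=conv_indices)


# -- input pipeline ---------------------------------------------------------

def prepare_images(images, size: int) -> np.ndarray:
    """Stack uint8 RGB patches into a normalised float32 NHWC batch.

    Downscaling by an integer factor uses exact block averaging; any other
    geometry falls back to skimage's resize.
    """
    out = np.empty((len(images), size, size, 3), dtype=np.float32)
    for i, img in enumerate(images):
        h, w = img.shape[:2]
        if h == w and h % size == 0:
            f = h // size
            small = (img.reshape(size, f, size, f, 3)
                        .mean(axis=(1, 3), dtype=np.float32))
        elif (h, w) == (size, size):
            small = img.astype(np.float32)
        else:
            small = _sk_resize(img, (size, size), preserve_range=True,
                               anti_aliasing=True).astype(np.float32)
        out[i] = small / 127.5 - 1.0
    return out


def _records_to_arrays(records: list[PatchRecord], size: int):
    X = prepare_images([r.image for r in records], size)
    y = np.array([1 if r.label == CARCINOMA else 0 for r in records])
    return X, y


# -- training ---------------------------------------------------------------

def train_patch_classifier(classifier: PatchClassifier, manifest,
                           config: TrainingConfig | None = None) -> PatchClassifier:
    """Train with Adam + categorical cross-entropy; return the classifier
    restored to its best-validation-accuracy checkpoint.

    ``manifest`` is a SplitManifest (training/validation splits are used) or
    a (train_records, val_records) pair. Raises if the training split does
    not contain both classes. classifier.log records per-epoch mean training
    loss and validation accuracy.
    """
    config = config or classifier.config
    if isinstance(manifest, SplitManifest):
        train_recs = manifest.subset("training")
        val_recs = manifest.subset("validation")
    else:
        train_recs, val_recs = manifest
    labels = {r.label for r in train_recs}
    if labels != {NORMAL, CARCINOMA}:
        raise ValueError(f"training split must contain both classes, got {labels}")
    if not val_recs:
        raise ValueError("validation split is empty")

    size = classifier.input_size
    Xtr, ytr = _records_to_arrays(train_recs, size)
    Xval, yval = _records_to_arrays(val_recs, size)

    rng = np.random.Generator(np.random.PCG64(config.seed + 1))
    opt = nn.Adam(classifier.net.parameters(), lr=config.learning_rate)
    rows = []
    best = (-1.0, -1, classifier.net.state_dict())
    for epoch in range(config.epochs):
        perm = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits = classifier.net.forward(Xtr[idx])
            loss, dlogits, _ = nn.softmax_cross_entropy(logits, ytr[idx])
            classifier.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_pred = _forward_in_batches(classifier, Xval).argmax(axis=1)
        val_acc = float((val_pred == yval).mean())
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_accuracy": val_acc})
        if val_acc > best[0]:  # strict: earliest epoch wins ties
            best = (val_acc, epoch, classifier.net.state_dict())
    if best[1] >= 0:
        classifier.net.load_state_dict(best[2])
        classifier.best_epoch = best[1]
        classifier.best_val_accuracy = best[0]
    classifier.log = pd.DataFrame(rows)
    return classifier


def _forward_in_batches(classifier: PatchClassifier, X: np.ndarray,
                        batch: int = 16) -> np.ndarray:
    outs = [classifier.net.forward(X[i:i + batch]) for i in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0)


def predict_patches(classifier: PatchClassifier,
                    patches: list[PatchRecord]) -> list[PatchPrediction]:
    """Softmax probabilities for each patch; background-flagged patches are
    predicted like any other (the flag is consumed downstream)."""
    if not patches:
        return []
    X = prepare_images([p.image for p in patches], classifier.input_size)
    probs = nn.softmax(_forward_in_batches(classifier, X))
    return [PatchPrediction(slide_id=p.slide_id, x=p.x, y=p.y,
                            p_normal=float(pr[0]), p_tumor=float(pr[1]))
            for p, pr in zip(patches, probs)]


# -- persistence ------------------------------------------------------------

def save_checkpoint(classifier: PatchClassifier, path: str | Path) -> None:
    """Weights as an .npz plus a JSON sidecar with config and best-epoch
    metadata; the training log goes to a sibling CSV when present."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(classifier.net.layers):
        for name, value in layer.params.items():
            arrays[f"{i}:{name}"] = value
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "backbone": classifier.config.backbone,
        "seed": classifier.config.seed,
        "input_size": classifier.input_size,
        "best_epoch": classifier.best_epoch,
        "best_val_accuracy": classifier.best_val_accuracy,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if classifier.log is not None:
        classifier.log.to_csv(path.with_suffix(".log.csv"), index=False)


def load_checkpoint(path: str | Path, config: TrainingConfig) -> PatchClassifier:
    path = Path(path)
    classifier = build_classifier(config)
    with np.load(path.with_suffix(".npz")) as data:
        for key in data.files:
            i, name = key.split(":")
            classifier.net.layers[int(i)].params[name] = data[key]
    meta = json.loads(path.with_suffix(".json").read_text())
    classifier.best_epoch = meta.get("best_epoch")
    classifier.best_val_accuracy = meta.get("best_val_accuracy")
    return classifier
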