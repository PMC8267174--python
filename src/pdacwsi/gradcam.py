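"""Grad-CAM attention maps for the patch classifier.

The class-specific gradient is propagated back to a convolutional layer's
feature maps; channel weights are the spatial means of those gradients, and
the attention map is the rectified weighted sum of the activations,
bilinearly upsampled to the input size and min-max normalised. The default
target is the last convolutional layer of the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .heatmap import probability_ramp
from .patch_model import PatchClassifier, prepare_images


@dataclass
class AttentionMap:
    """H x W attention in [0, 1]; all-zero when the target class receives
    no positive gradient-weighted activation."""

    values: np.ndarray
    target_class: int
    layer_name: str


def grad_cam(classifier: PatchClassifier, image: np.ndarray,
             target_class: int, layer: int | None = None) -> AttentionMap:
    """Attention map of ``target_class`` for one RGB patch.

    ``layer`` is an index into the classifier's network and must point at a
    convolutional layer; by default the backbone's last convolution is
    used. The map is returned at the patch's own resolution.
    """
    net = classifier.net
    if layer is None:
        layer = classifier.conv_indices[-1]
    if not isinstance(net.layers[layer], nn.Conv2D):
        raise ValueError(f"layer {layer} ({type(net.layers[layer]).__name__}) "
                         "is not convolutional")
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 (normal) or 1 (tumor)")

    x = prepare_images([image], classifier.input_size)
    logits, acts = net.forward(x, record={layer})
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    _, grads = net.backward(dlogits, record={layer})

    activation = acts[layer][0]          # (h, w, C)
    grad = grads[layer][0]               # (h, w, C)
    weights = grad.mean(axis=(0, 1))     # spatially averaged gradients
    cam = np.maximum((activation * weights).sum(axis=-1), 0.0)

    out_shape = image.shape[:2]
    if cam.shape != out_shape:
        cam = _sk_resize(cam, out_shape, order=1, preserve_range=True)
    lo, hi = float(cam.min()), float(cam.max())
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros(out_shape)
    return AttentionMap(values=cam, target_class=target_class,
                        layer_name=f"conv@{layer}")


def render_comparison(patch: np.ndarray, mask: np.ndarray,
                      attention: AttentionMap | np.ndarray,
                      seg_heatmap: np.ndarray,
                      margin: int = 8) -> np.ndarray:
    """Four-panel composite: raw patch | annotation mask | Grad-CAM |
    segmentation heatmap, separated by white margins.

    All inputs must be aligned to the same patch geometry. The mask and the
    segmentation map are rendered on the dark-blue -> crimson ramp, the
    attention map in grayscale.
    """
    att = attention.values if isinstance(attention, AttentionMap) else attention
    h, w = patch.shape[:2]
    for name, arr in (("mask", mask), ("attention", att),
                      ("segmentation heatmap", seg_heatmap)):
        if arr.shape[:2] != (h, w):
            raise ValueError(f"{name} shape {arr.shape[:2]} does not match "
                             f"patch {h}x{w}")
    panels = [
        patch.astype(np.uint8),
        probability_ramp(mask.astype(float)),
        np.repeat(np.rint(att * 255).astype(np.uint8)[..., None], 3, axis=-1),
        probability_ramp(np.asarray(seg_heatmap, dtype=float)),
    ]
    gap = np.full((h, margin, 3), 255, dtype=np.uint8)
    strips: list[np.ndarray] = []
    for i, panel in enumerate(panels):
        if i:
            strips.append(gap)
        strips.append(panel)
    return np.concatenate(strips, axis=1)
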