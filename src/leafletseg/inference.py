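"""Prediction and post-processing.

Inference is a single full-ROI forward pass on the same channel stack layout
used in training (no augmentation, no tiling); the label map is the per-voxel
argmax of the four softmax channels, ties broken toward the lowest class
index.  Post-processing keeps only the largest 26-connected component per
leaflet; holes are left alone (hole filling is a ground-truth cleanup step,
not an inference step).
"""

from __future__ import annotations

import numpy as np

from .core import LeafletLabelMap
from .encoding import ChannelStack
from .network import VNet, forward_probs
from .preprocess import largest_component

__all__ = ["predict", "postprocess"]


def predict(model: VNet, stack: ChannelStack) -> LeafletLabelMap:
    """Per-voxel argmax segmentation of a channel stack."""
    probs = forward_probs(model, stack)
    labels = np.argmax(probs, axis=0).astype(np.uint8)  # np.argmax takes the first maximum
    return LeafletLabelMap(labels=labels, grid=stack.grid)


def postprocess(pred: LeafletLabelMap) -> LeafletLabelMap:
    """Keep only the largest 26-connected component of every leaflet label."""
    out = np.zeros_like(pred.labels)
    for label in pred.present_labels():
        out[largest_component(pred.labels == label)] = label
    return LeafletLabelMap(labels=out, grid=pred.grid)
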