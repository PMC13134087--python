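"""Grad-CAM++ attention maps for the response classifier and IoU scoring
of attention against lesion masks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.ndimage import zoom

from .cases import LongitudinalCase
from .evalmetrics import _check_binary
from .network import ModelBundle
from .nn.tensor import Tensor


@dataclass
class AttentionMap:
    """Max-normalized nonnegative heatmap at input resolution."""

    heatmap: np.ndarray
    layer: int
    case_id: str = ""


def _gradcam_pp_weights(acts: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """Per-channel Grad-CAM++ weights from activations and gradients.

    Uses the closed-form alpha with elementwise gradient powers:
    ``alpha = g^2 / (2 g^2 + sum_spatial(A) * g^3)`` and
    ``w_c = sum_spatial(alpha * relu(g))``.  When the activation map is
    spatially uniform this reduces to the plain gradient-averaging
    weights (up to the shared normalization), i.e. Grad-CAM.
    """
    g2 = grads ** 2
    g3 = grads ** 3
    denom = 2.0 * g2 + acts.sum(axis=(1, 2), keepdims=True) * g3
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(
        np.abs(denom) > 1e-12, denom, 1.0), 0.0)
    return (alpha * np.maximum(grads, 0.0)).sum(axis=(1, 2))


def grad_cam_pp_map(acts: np.ndarray, grads: np.ndarray,
                    out_shape: Optional[Sequence[int]] = None) -> np.ndarray:
    """Heatmap from raw (C, h, w) activations and matching gradients.

    This is the model-agnostic core of :func:`grad_cam_pp`: channel
    weights, rectified weighted sum, optional bilinear upsampling,
    max-normalization.
    """
    acts = np.asarray(acts, dtype=np.float64)
    grads = np.asarray(grads, dtype=np.float64)
    if acts.shape != grads.shape or acts.ndim != 3:
        raise ValueError("expected matching (C, h, w) arrays")
    weights = _gradcam_pp_weights(acts, grads)
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    if out_shape is not None and tuple(out_shape) != cam.shape:
        cam = zoom(cam, (out_shape[0] / cam.shape[0],
                         out_shape[1] / cam.shape[1]), order=1)
        cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return np.clip(cam, 0.0, 1.0)


def grad_cam_pp(bundle: ModelBundle, image: np.ndarray,
                layer: int = -2) -> AttentionMap:
    """Grad-CAM++ heatmap of the pCR logit over one pre-treatment stack.

    Gradients are taken at the chosen encoder stage with respect to the
    pre-sigmoid logit; the channel-weighted activation sum is rectified,
    bilinearly upsampled to the input size and max-normalized.  The
    default stage is the penultimate one — the last stage with enough
    spatial resolution to localize lesion-scale structure (the 8x8
    latent map is too coarse for attention maps).
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3:
        img = img[None]
    x = Tensor(img)
    _, stage_acts = bundle.G.encoder(x, return_stages=True)
    layer_idx = layer % len(stage_acts)
    target_act = stage_acts[layer_idx]
    z = stage_acts[-1]
    logit = bundle.head.logit(z)
    for m in (bundle.G, bundle.head):
        m.zero_grad()
    logit.backward(np.ones_like(logit.data))
    if target_act.grad is None or not np.any(target_act.grad):
        warnings.warn("grad_cam_pp: zero gradient everywhere, returning "
                      "all-zero map", RuntimeWarning, stacklevel=2)
        h, w = img.shape[2], img.shape[3]
        return AttentionMap(np.zeros((h, w)), layer_idx)
    acts = target_act.data[0].astype(np.float64)
    grads = target_act.grad[0].astype(np.float64)
    cam_up = grad_cam_pp_map(acts, grads,
                             out_shape=(img.shape[2], img.shape[3]))
    return AttentionMap(cam_up, layer_idx)


def cam_to_mask(attention: AttentionMap,
                threshold_fraction: float = 0.5) -> np.ndarray:
    """Binarize a heatmap at a fraction of its maximum."""
    hm = attention.heatmap
    peak = hm.max()
    if peak == 0:
        return np.zeros_like(hm, dtype=np.uint8)
    return (hm >= threshold_fraction * peak).astype(np.uint8)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """``|A∩B| / |A∪B|``; two empty masks score 1 by convention."""
    a = _check_binary(mask_a, "mask_a")
    b = _check_binary(mask_b, "mask_b")
    if a.shape != b.shape:
        raise ValueError("iou: shape mismatch")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def iou_cohort_report(bundles: Dict[str, ModelBundle],
                      cases: Sequence[LongitudinalCase],
                      layer: int = -2,
                      threshold_fraction: float = 0.5) -> Dict[str, Dict]:
    """Per-model distributions of attention-vs-lesion IoU.

    For each model and case: Grad-CAM++ on the pre-treatment stack,
    binarized at ``threshold_fraction`` of the peak, scored against the
    lesion mask.  Deterministic (no sampling involved).
    """
    if not bundles:
        raise ValueError("need at least one bundle")
    report: Dict[str, Dict] = {}
    for name, bundle in bundles.items():
        values = []
        for c in cases:
            if c.lesion_mask is None:
                raise ValueError(f"case {c.patient_id} has no lesion mask")
            att = grad_cam_pp(bundle, c.pre_image, layer=layer)
            values.append(iou(cam_to_mask(att, threshold_fraction),
                              c.lesion_mask))
        arr = np.asarray(values)
        report[name] = {
            "iou": arr,
            "median": float(np.median(arr)),
            "q1": float(np.quantile(arr, 0.25)),
            "q3": float(np.quantile(arr, 0.75)),
        }
    return report
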