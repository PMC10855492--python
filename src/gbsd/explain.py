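"""Saliency: Grad-CAM++, FullGrad, guided backprop, and their fusion.

All three methods operate on a :class:`gbsd.nn.Sequential` classifier and a
batch-of-one input, differentiating the pre-softmax logit of a target class:

* **Grad-CAM++** — a ReLU-rectified weighted sum of the last convolutional
  block's activation maps, the per-map weights being spatial sums of
  gradient-derived alpha coefficients (built from elementwise powers of the
  first-order gradient) times the positive gradients.
* **FullGrad** — the full-gradient decomposition: the input-gradient term
  ``|x * dY/dx|`` plus per-layer bias-gradient contributions, which for a
  piecewise-linear (ReLU) network reconstruct the logit exactly
  (completeness), each term rectified and aggregated to one map.
* **Guided backprop** — the input gradient with negative upstream gradients
  suppressed at every ReLU, giving crisp pixel-space structure; multiplied
  with an upsampled class-discriminative map it yields the GP-CAM /
  GP-FullGrad visualizations.

Grad-CAM++ and FullGrad maps are min-max normalized to [0, 1] (so neither
dominates by scale) and fused by elementwise averaging into the map ``OH``
that the explainable classifier consumes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize

from . import nn

MAP_SIZE = 128
_EPS = 1e-12


@dataclasses.dataclass
class SaliencyBundle:
    """The saliency maps produced for one input and one class."""

    H: np.ndarray  # Grad-CAM++ map, >= 0, (128, 128), normalized
    P: np.ndarray  # FullGrad map, (128, 128), normalized
    GP: np.ndarray  # guided-backprop pixel-space map, (128, 128)
    OH: np.ndarray  # fused map (H + P) / 2, (128, 128)
    class_index: int


def _normalize(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi - lo <= _EPS:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def _to_map(m: np.ndarray, shape: tuple[int, int] = (MAP_SIZE, MAP_SIZE)) -> np.ndarray:
    if m.shape != shape:
        m = resize(m, shape, anti_aliasing=False)
    return m


def _onehot_grad(logits: np.ndarray, q: int) -> np.ndarray:
    n_classes = logits.shape[-1]
    if not 0 <= q < n_classes:
        raise ValueError(f"class index {q} out of range [0, {n_classes})")
    g = np.zeros_like(logits)
    g[:, q] = 1.0
    return g


def _last_conv_relu_index(net: nn.Sequential) -> int:
    """Index of the ReLU following the last spatial convolution."""
    idx = None
    for i, layer in enumerate(net.layers):
        if isinstance(layer, nn.ReLU) and i > 0 and isinstance(net.layers[i - 1], nn.Conv2d):
            if net.layers[i - 1].k > 1:
                idx = i
    if idx is None:
        raise ValueError("network has no conv->ReLU block")
    return idx


def gradcampp(
    net: nn.Sequential, x: np.ndarray, q: int, conv_index: int | None = None
) -> np.ndarray:
    """Grad-CAM++ map for class ``q``, upsampled to 128x128, in [0, 1].

    ``H = relu(sum_l w_l A^l)`` over the last conv block's rectified
    activation maps ``A^l``; ``w_l = sum_ij alpha_ij * relu(dY/dA_ij)`` with
    ``alpha = g^2 / (2 g^2 + sum_ij A g^3)``, g the logit gradient.
    """
    if x.ndim != 4 or x.shape[0] != 1:
        raise ValueError("x must be a (1, C, H, W) batch")
    if conv_index is None:
        conv_index = _last_conv_relu_index(net)
    logits = net.forward(x, train=False)
    A = net.outputs[conv_index]  # (1, L, h, w)
    g = net.backward(_onehot_grad(logits, q), upto=conv_index + 1)
    return _gradcam_from(A, g, x.shape[2:])


def _gradcam_from(
    A: np.ndarray, g: np.ndarray, shape: tuple[int, int] = (MAP_SIZE, MAP_SIZE)
) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    g2, g3 = g**2, g**3
    denom = 2.0 * g2 + (A * g3).sum(axis=(2, 3), keepdims=True)
    alpha = np.where(np.abs(denom) > _EPS, g2 / np.where(np.abs(denom) > _EPS, denom, 1.0), 0.0)
    w = (alpha * np.maximum(g, 0.0)).sum(axis=(2, 3))  # (1, L)
    H = np.maximum((w[:, :, None, None] * A).sum(axis=1)[0], 0.0)
    return _normalize(_to_map(H, shape))


def fullgrad_components(
    net: nn.Sequential, x: np.ndarray, q: int
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]], float]:
    """Raw full-gradient pieces for class ``q``.

    Returns ``(input_grad, [(bias, bias_grad), ...], logit)``; for a ReLU
    network ``logit == (input_grad * x).sum() + sum(bias . bias_grad)``
    (completeness of the decomposition).
    """
    logits = net.forward(x, train=False)
    gin = net.backward(_onehot_grad(logits, q))
    bias_terms: list[tuple[np.ndarray, np.ndarray]] = []
    for layer in net.layers:
        if isinstance(layer, (nn.Conv2d, nn.Dense)) and layer.b is not None:
            bias_terms.append((layer.b, layer.bias_grad_map))
    return gin, bias_terms, float(logits[0, q])


def fullgrad(net: nn.Sequential, x: np.ndarray, q: int) -> np.ndarray:
    """FullGrad saliency map for class ``q``, 128x128, normalized to [0, 1].

    ``P = |x . dY/dx|`` (summed over channels) plus each spatial bias-gradient
    contribution ``|b_c * dY/d(pre-activation)_c|`` resized to the input
    size.  A model without biases degrades to the input-gradient term alone.
    """
    gin, bias_terms, _ = fullgrad_components(net, x, q)
    return _fullgrad_from(x, gin, bias_terms)


def _fullgrad_from(
    x: np.ndarray, gin: np.ndarray, bias_terms: list[tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    shape = x.shape[2:]
    P = _to_map(np.abs(np.asarray(x[0], dtype=np.float64) * gin[0]).sum(axis=0), shape)
    for b, gmap in bias_terms:
        if gmap is None:
            continue
        if gmap.ndim == 4:  # conv bias: (1, C, h, w), spatially resolved
            contrib = np.abs(
                np.asarray(b, dtype=np.float64)[None, :, None, None] * gmap
            )[0].sum(axis=0)
            P = P + _to_map(_normalize(contrib), shape)
        # dense biases contribute a spatially uniform term: invisible after
        # min-max normalization, so they are accounted for only in the
        # completeness check
    return _normalize(P)


def guided_backprop(net: nn.Sequential, x: np.ndarray, q: int) -> np.ndarray:
    """Input-space gradient with negative gradients zeroed at each ReLU."""
    logits = net.forward(x, train=False)
    gin = net.backward(_onehot_grad(logits, q), guided=True)
    return _to_map(np.abs(gin[0]).sum(axis=0), x.shape[2:])


def fuse_saliency(H: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Elementwise average of the two saliency maps: ``OH = (H + P) / 2``."""
    H = np.asarray(H, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    if H.shape != P.shape:
        raise ValueError(f"shape mismatch: H {H.shape} vs P {P.shape}")
    return (H + P) / 2.0


def fused_maps(
    net: nn.Sequential, x: np.ndarray, q: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Grad-CAM++ and FullGrad maps from one shared forward/backward pass.

    Numerically equivalent to calling :func:`gradcampp` and :func:`fullgrad`
    separately (same weights, same caches), at roughly half the cost.
    Returns ``(H, P, OH, q)``.
    """
    conv_index = _last_conv_relu_index(net)
    logits = net.forward(x, train=False)
    if q is None:
        q = int(np.argmax(logits[0]))
    gin = net.backward(_onehot_grad(logits, q), record=True)
    A = net.outputs[conv_index]
    g = net.grad_outputs[conv_index]
    H = _gradcam_from(A, g, x.shape[2:])
    bias_terms = [
        (layer.b, layer.bias_grad_map)
        for layer in net.layers
        if isinstance(layer, (nn.Conv2d, nn.Dense)) and layer.b is not None
    ]
    P = _fullgrad_from(x, gin, bias_terms)
    return H, P, fuse_saliency(H, P), q


def saliency_bundle(
    net: nn.Sequential, x: np.ndarray, q: int | None = None
) -> SaliencyBundle:
    """Compute all maps for one input; ``q`` defaults to the predicted class."""
    logits = net.forward(x, train=False)
    if q is None:
        q = int(np.argmax(logits[0]))
    H = gradcampp(net, x, q)
    P = fullgrad(net, x, q)
    GP = guided_backprop(net, x, q)
    return SaliencyBundle(H=H, P=P, GP=GP, OH=fuse_saliency(H, P), class_index=q)
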