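"""Grid-based texture descriptors and the concatenated feature stack.

Four families of per-pixel feature maps are computed on the 128x128 lesion
ROI and concatenated channel-wise into the classifier input:

* **grid structural pattern** — a local-binary-pattern (LBP) variant: for a
  pixel, every one of the nine pixels in its 3x3 cell serves as an LBP
  center (8 neighbours, threshold at the center, equality counts as 1), and
  the cell value is the mean of the nine 8-bit codes.  Averaging over the
  cell damps the intensity sensitivity of plain LBP.
* **grid directional pattern** — a local-directional-pattern (LDP) map: the
  eight Kirsch compass masks are convolved with the image and, per pixel,
  the bits of the ``m`` strongest responses are set (ties resolved toward
  the lower orientation index), yielding codes of popcount ``m``.
* **statistical maps** — windowed mean, median and mode of the intensities
  (mode over 8-bit quantized values, ties toward the smallest value).
* **deep maps** — activations of a convolutional backbone, reduced to ``k``
  channels by a 1x1 projection and resized to 128x128.

All descriptor maps use reflective border padding.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage, stats
from skimage.transform import resize

from . import nn

MAP_SIZE = 128

# Neighbor offsets (dy, dx) for LBP bit d in [0, 8): top-left then clockwise.
LBP_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

# The eight 3x3 Kirsch compass masks, orientation index n in [0, 8)
# (E, NE, N, NW, W, SW, S, SE).  Each mask's coefficients sum to zero.
KIRSCH_MASKS = np.array(
    [
        [[-3, -3, 5], [-3, 0, 5], [-3, -3, 5]],
        [[-3, 5, 5], [-3, 0, 5], [-3, -3, -3]],
        [[5, 5, 5], [-3, 0, -3], [-3, -3, -3]],
        [[5, 5, -3], [5, 0, -3], [-3, -3, -3]],
        [[5, -3, -3], [5, 0, -3], [5, -3, -3]],
        [[-3, -3, -3], [5, 0, -3], [5, 5, -3]],
        [[-3, -3, -3], [-3, 0, -3], [5, 5, 5]],
        [[-3, -3, -3], [-3, 0, 5], [-3, 5, 5]],
    ],
    dtype=np.float64,
)


@dataclasses.dataclass(frozen=True)
class LBPContext:
    """3x3 LBP: D=8 neighbours at distance S=1, bit d weighted 2**d."""

    D: int = 8
    S: int = 1

    def __post_init__(self) -> None:
        if (self.D, self.S) != (8, 1):
            raise ValueError("the 3x3 grid descriptor requires D=8, S=1")


@dataclasses.dataclass(frozen=True)
class LDPContext:
    """Kirsch LDP with the top ``m`` of 8 responses set (tie: lower index)."""

    m: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.m <= 7:
            raise ValueError("m must be in [1, 7]")


@dataclasses.dataclass(frozen=True)
class StatContext:
    """Windowed statistics; mode over 8-bit quantization, ties -> smallest."""

    window: int = 3

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")


@dataclasses.dataclass
class FeatureStack:
    """Concatenated multi-channel descriptor tensor feeding the classifier.

    ``data`` is the (C, 128, 128) stack with every channel min-max
    normalized to [0, 1] (constant channels map to 0); ``names`` labels the
    channels in order; ``provenance`` records per-channel parameters.
    """

    data: np.ndarray
    names: list[str]
    provenance: dict

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1:] != (MAP_SIZE, MAP_SIZE):
            raise ValueError(f"stack must be (C, {MAP_SIZE}, {MAP_SIZE}), got {self.data.shape}")
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per channel required")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            data=self.data,
            header=json.dumps({"names": self.names, "provenance": self.provenance}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureStack":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            return cls(data=z["data"], names=header["names"], provenance=header["provenance"])


def _require_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("descriptor maps require a single-channel image; reduce to luminance first")
    return img


def lbp_code(patch: np.ndarray, ctx: LBPContext = LBPContext()) -> int:
    """8-bit LBP code of a 3x3 patch (equality with the center counts as 1)."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (3, 3):
        raise ValueError(f"patch must be 3x3, got {patch.shape}")
    center = patch[1, 1]
    code = 0
    for d, (dy, dx) in enumerate(LBP_OFFSETS):
        if patch[1 + dy, 1 + dx] - center >= 0:
            code |= 1 << d
    return code


def lbp_code_map(img: np.ndarray, ctx: LBPContext = LBPContext()) -> np.ndarray:
    """Per-pixel 8-bit LBP codes with reflective border padding."""
    img = _require_gray(img)
    # edge-repeating reflection, matching scipy.ndimage's "reflect" mode
    p = np.pad(img, 1, mode="symmetric")
    h, w = img.shape
    code = np.zeros((h, w), dtype=np.int64)
    for d, (dy, dx) in enumerate(LBP_OFFSETS):
        neigh = p[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        code |= (neigh >= img).astype(np.int64) << d
    return code


def grid_structural_map(img: np.ndarray, ctx: LBPContext = LBPContext()) -> np.ndarray:
    """Mean of the nine per-pixel LBP codes within each 3x3 cell.

    Every pixel of the cell acts as its own LBP center; out-of-image cell
    members mirror across the border (reflect padding), consistently with
    the per-pixel code computation.  Values lie in [0, 255].
    """
    codes = lbp_code_map(img, ctx).astype(np.float64)
    return ndimage.uniform_filter(codes, size=3, mode="reflect")


def kirsch_responses(img: np.ndarray, ctx: LDPContext = LDPContext()) -> np.ndarray:
    """The 8 Kirsch compass responses, shape (8, H, W), reflect padding."""
    img = _require_gray(img)
    return np.stack(
        [ndimage.correlate(img, m, mode="reflect") for m in KIRSCH_MASKS]
    )


def ldp_code_map(img: np.ndarray, ctx: LDPContext = LDPContext()) -> np.ndarray:
    """Per-pixel LDP codes: bit n set when response n is among the top m.

    Ties are broken toward the lower orientation index, so every code has
    popcount exactly ``ctx.m``.
    """
    resp = kirsch_responses(img, ctx)
    # stable argsort on -resp: equal responses keep ascending orientation order
    order = np.argsort(-resp, axis=0, kind="stable")
    top = order[: ctx.m]
    return np.sum(1 << top, axis=0).astype(np.int64)


def statistical_maps(img: np.ndarray, ctx: StatContext = StatContext()) -> dict[str, np.ndarray]:
    """Windowed mean, median and mode maps (reflect padding).

    The mode is taken over 8-bit quantized intensities ([0, 1] scale assumed)
    with ties resolved toward the smallest value, then mapped back to [0, 1].
    The window is odd, so the windowed median is the exact middle order
    statistic; for even sample counts it would be the average of the two
    middle values.
    """
    img = _require_gray(img)
    w = ctx.window
    mean = ndimage.uniform_filter(img, size=w, mode="reflect")
    median = ndimage.median_filter(img, size=w, mode="reflect")
    q = np.round(img * 255.0)
    sw = np.lib.stride_tricks.sliding_window_view(
        np.pad(q, w // 2, mode="reflect"), (w, w)
    ).reshape(img.shape[0], img.shape[1], w * w)
    mode = stats.mode(sw, axis=-1).mode / 255.0
    return {"stat_mean": mean, "stat_median": median, "stat_mode": mode}


# ---------------------------------------------------------------------------
# deep backbone
# ---------------------------------------------------------------------------

_SMALL_CNN_SEED = 20240126  # fixed: backbone weights are part of the artifact


def _small_cnn(k: int, bias: bool = True, projection: np.ndarray | None = None) -> nn.Sequential:
    """Deterministic random-projection conv backbone (2 blocks + 1x1 head).

    The fixed-seed random convolution stack acts as a generic multiscale
    filter bank; the classifier that consumes the maps is what gets trained.
    """
    rng = np.random.default_rng(_SMALL_CNN_SEED)
    conv1 = nn.Conv2d(1, 8, 3, rng, bias=bias)
    conv2 = nn.Conv2d(8, 16, 3, rng, bias=bias)
    proj = nn.Conv2d(16, k, 1, rng, bias=False)
    if projection is not None:
        proj.W[...] = projection.reshape(k, 16)
    return nn.Sequential(
        [conv1, nn.ReLU(), nn.MaxPool2d(2), conv2, nn.ReLU(), nn.MaxPool2d(2), proj]
    )


# VGG-16 convolutional layout: filters per conv layer, pooling after the
# marked indices.  Weights must be supplied locally as an .npz with arrays
# conv{i}_W of shape (cout, cin, 3, 3) and conv{i}_b of shape (cout,).
VGG16_FILTERS = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512)
VGG16_POOL_AFTER = frozenset({1, 3, 6, 9, 12})
VGG16_INPUT = 224


def _vgg16_from_npz(weights_path: str | Path, k: int) -> nn.Sequential:
    z = np.load(weights_path)
    rng = np.random.default_rng(_SMALL_CNN_SEED)
    layers: list[nn.Layer] = []
    cin = 1
    for i, cout in enumerate(VGG16_FILTERS):
        conv = nn.Conv2d(cin, cout, 3, rng)
        W = z[f"conv{i}_W"]
        if W.shape != (cout, cin, 3, 3):
            raise ValueError(f"conv{i}_W has shape {W.shape}, expected {(cout, cin, 3, 3)}")
        conv.W[...] = W.reshape(cout, -1)
        conv.b[...] = z[f"conv{i}_b"]
        layers += [conv, nn.ReLU()]
        if i in VGG16_POOL_AFTER:
            layers.append(nn.MaxPool2d(2))
        cin = cout
    proj = nn.Conv2d(cin, k, 1, rng, bias=False)
    layers.append(proj)
    return nn.Sequential(layers)


def deep_features(
    img: np.ndarray,
    backbone: str = "small_cnn",
    k: int = 8,
    weights_path: str | Path | None = None,
) -> np.ndarray:
    """Backbone activation maps, 1x1-projected to ``k`` channels, 128x128.

    ``small_cnn`` (default) needs no external weights.  ``vgg16`` runs only
    from a locally supplied ``weights_path`` .npz; nothing is ever
    downloaded.
    """
    img = _require_gray(img)
    if backbone == "small_cnn":
        net = _small_cnn(k)
        x = resize(img, (MAP_SIZE, MAP_SIZE), anti_aliasing=True)
    elif backbone == "vgg16":
        if weights_path is None or not Path(weights_path).exists():
            raise FileNotFoundError(
                "vgg16 backbone requires a local weights file (.npz with conv{i}_W/"
                "conv{i}_b arrays); acquire it offline and pass weights_path — "
                "no weights are downloaded automatically"
            )
        net = _vgg16_from_npz(weights_path, k)
        x = resize(img, (VGG16_INPUT, VGG16_INPUT), anti_aliasing=True)
    else:
        raise ValueError(f"unknown backbone {backbone!r}")
    maps = net.forward(x[None, None, :, :])[0]
    out = np.stack([resize(m, (MAP_SIZE, MAP_SIZE), anti_aliasing=False) for m in maps])
    return out


def _minmax(ch: np.ndarray) -> np.ndarray:
    lo, hi = ch.min(), ch.max()
    if hi - lo == 0:
        return np.zeros_like(ch)
    return (ch - lo) / (hi - lo)


def concat_features(
    lbp: np.ndarray,
    ldp: np.ndarray,
    stat: dict[str, np.ndarray],
    deep: np.ndarray,
    provenance: dict | None = None,
) -> FeatureStack:
    """Concatenate descriptor channels in fixed order, min-max normalized.

    Order: lbp, ldp, stat_mean, stat_median, stat_mode, deep_0..deep_{k-1}.
    A constant channel normalizes to all zeros.
    """
    named: list[tuple[str, np.ndarray]] = [("lbp", lbp), ("ldp", ldp)]
    for key in ("stat_mean", "stat_median", "stat_mode"):
        named.append((key, stat[key]))
    for i, d in enumerate(np.asarray(deep, dtype=np.float64)):
        named.append((f"deep_{i}", d))
    for name, ch in named:
        ch = np.asarray(ch)
        if ch.shape != (MAP_SIZE, MAP_SIZE):
            raise ValueError(f"channel {name!r} has shape {ch.shape}, expected {(MAP_SIZE, MAP_SIZE)}")
    data = np.stack([_minmax(np.asarray(ch, dtype=np.float64)) for _, ch in named])
    return FeatureStack(
        data=data,
        names=[n for n, _ in named],
        provenance=provenance or {},
    )


def extract_features(
    roi: np.ndarray,
    lbp_ctx: LBPContext = LBPContext(),
    ldp_ctx: LDPContext = LDPContext(),
    stat_ctx: StatContext = StatContext(),
    backbone: str = "small_cnn",
    k: int = 8,
    weights_path: str | Path | None = None,
) -> FeatureStack:
    """Full descriptor stack of a 128x128 lesion ROI."""
    roi = _require_gray(roi)
    if roi.shape != (MAP_SIZE, MAP_SIZE):
        roi = resize(roi, (MAP_SIZE, MAP_SIZE), anti_aliasing=True)
    lbp = grid_structural_map(roi, lbp_ctx)
    ldp = ldp_code_map(roi, ldp_ctx).astype(np.float64)
    stat = statistical_maps(roi, stat_ctx)
    deep = deep_features(roi, backbone=backbone, k=k, weights_path=weights_path)
    prov = {
        "lbp": dataclasses.asdict(lbp_ctx),
        "ldp": dataclasses.asdict(ldp_ctx),
        "stat": dataclasses.asdict(stat_ctx),
        "deep": {"backbone": backbone, "k": k},
    }
    return concat_features(lbp, ldp, stat, deep, provenance=prov)
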