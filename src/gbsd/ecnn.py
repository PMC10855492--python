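"""The explainable CNN (ECNN) classifier.

Architecture: a shared trunk of three conv -> ReLU -> max-pool blocks
followed by dropout, a fully connected layer and a softmax head over the two
classes (benign / malignant).  Two 1x1 "adapter" convolutions feed the
trunk: one maps the multi-channel feature stack (pass 1), the other the
single-channel fused saliency map ``OH`` (pass 2); all remaining weights are
shared between the passes.

The classifier's data flow is circular by design — features produce a
prediction, the prediction's saliency produces the fused map, and the fused
map is what the final classification consumes.  This is resolved as a
two-pass scheme with a warm-up phase: early epochs train on the raw feature
stack only (the saliency of an untrained network is noise), after which the
fused maps are generated from the current network, cached, periodically
refreshed, and trained on alongside the raw stack.  Inference always
reports the pass-2 (saliency-map) probabilities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pickle
from pathlib import Path

import numpy as np

from . import nn
from .explain import (
    SaliencyBundle,
    fuse_saliency,
    fused_maps,
    fullgrad,
    gradcampp,
    guided_backprop,
)

log = logging.getLogger("gbsd.ecnn")

N_CLASSES = 2
LABEL_NAMES = ("benign", "malignant")  # index 0 / 1; malignant is "positive"


@dataclasses.dataclass
class ECNNConfig:
    """Hyperparameters of the explainable CNN (AICO-tunable)."""

    conv_filters: tuple[int, int, int] = (8, 16, 32)
    kernel_size: int = 3
    pool: tuple[int, int, int] = (2, 2, 2)
    dropout_rate: float = 0.25
    fc_units: int = 32
    learning_rate: float = 0.005
    batch_size: int = 16
    epochs: int = 20
    stem_channels: int = 8
    input_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(c) for c in self.conv_filters)
        self.pool = tuple(int(p) for p in self.pool)
        if len(self.conv_filters) != 3 or len(self.pool) != 3:
            raise ValueError("exactly 3 conv+pool blocks are required")
        if any(c < 1 for c in self.conv_filters) or self.fc_units < 1 or self.batch_size < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclasses.dataclass
class TrainReport:
    """Per-epoch training trace plus the configuration snapshot."""

    train_loss: list[float]
    train_acc: list[float]
    val_loss: list[float]
    val_acc: list[float]
    val_confusion: list[tuple[int, int, int, int]]  # (tp, tn, fp, fn) per epoch
    seed: int
    config: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


class ECNNModel:
    """Shared-trunk two-pass classifier (see module docstring)."""

    def __init__(self, cfg: ECNNConfig, in_channels: int):
        size = cfg.input_size
        for p in cfg.pool:
            if size % p:
                raise ValueError(f"pool size {p} does not divide spatial size {size}")
            size //= p
        if size < 1:
            raise ValueError("pooling collapses the spatial dimensions below 1x1")
        self.cfg = cfg
        self.in_channels = in_channels
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xECC)))
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xD60)))

        c1, c2, c3 = cfg.conv_filters
        k = cfg.kernel_size
        self.adapter_stack = nn.Conv2d(in_channels, cfg.stem_channels, 1, rng)
        self.adapter_saliency = nn.Conv2d(1, cfg.stem_channels, 1, rng)
        trunk: list[nn.Layer] = []
        cin = cfg.stem_channels
        for cout, p in zip((c1, c2, c3), cfg.pool):
            trunk += [nn.Conv2d(cin, cout, k, rng), nn.ReLU(), nn.MaxPool2d(p)]
            cin = cout
        trunk += [
            nn.Dropout(cfg.dropout_rate, self._dropout_rng),
            nn.Flatten(),
            nn.Dense(c3 * size * size, cfg.fc_units, rng),
            nn.ReLU(),
            nn.Dense(cfg.fc_units, N_CLASSES, rng),
        ]
        self.trunk = trunk
        self.pass1 = nn.Sequential([self.adapter_stack] + trunk)
        self.pass2 = nn.Sequential([self.adapter_saliency] + trunk)

    def n_params(self) -> int:
        seen, total = set(), 0
        for net in (self.pass1, self.pass2):
            for p in net.params:
                if id(p) not in seen:
                    seen.add(id(p))
                    total += p.size
        return total

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        params = self.pass1.state() + [self.adapter_saliency.W.copy(), self.adapter_saliency.b.copy()]
        with open(path, "wb") as fh:
            pickle.dump(
                {"cfg": dataclasses.asdict(self.cfg), "in_channels": self.in_channels, "params": params},
                fh,
            )
        meta = {"cfg": dataclasses.asdict(self.cfg), "in_channels": self.in_channels}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ECNNModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        cfg = ECNNConfig(**blob["cfg"])
        model = cls(cfg, blob["in_channels"])
        params = blob["params"]
        model.pass1.load_state(params[:-2])
        model.adapter_saliency.W[...] = params[-2]
        model.adapter_saliency.b[...] = params[-1]
        return model


def build_model(cfg: ECNNConfig, in_channels: int) -> ECNNModel:
    """Construct the classifier; parameter count is deterministic in cfg."""
    return ECNNModel(cfg, in_channels)


def forward_two_pass(
    model: ECNNModel, stack: np.ndarray
) -> tuple[np.ndarray, SaliencyBundle]:
    """Run the full explainable forward scheme on one feature stack.

    Pass 1 classifies the raw stack and yields the predicted class ``q``;
    Grad-CAM++ and FullGrad maps for ``q`` are fused into ``OH``; pass 2
    classifies ``OH``.  Returns the pass-2 class probabilities and the
    saliency bundle (whose ``OH`` is exactly the pass-2 input).
    """
    x = np.asarray(stack, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1] != model.in_channels:
        raise ValueError(f"expected {model.in_channels} channels, got {x.shape[1]}")
    logits1 = model.pass1.forward(x, train=False)
    q = int(np.argmax(logits1[0]))
    H = gradcampp(model.pass1, x, q)
    P = fullgrad(model.pass1, x, q)
    GP = guided_backprop(model.pass1, x, q)
    OH = fuse_saliency(H, P)
    logits2 = model.pass2.forward(OH[None, None], train=False)
    probs = nn.softmax(logits2)[0]
    return probs, SaliencyBundle(H=H, P=P, GP=GP, OH=OH, class_index=q)


def _fused_map(model: ECNNModel, x1: np.ndarray) -> np.ndarray:
    _, _, OH, _ = fused_maps(model.pass1, x1[None])
    return OH


def _epoch_pass(model, X, y, idx, opt, which: str) -> tuple[float, float]:
    net = model.pass1 if which == "stack" else model.pass2
    losses, correct = [], 0
    bs = model.cfg.batch_size
    for start in range(0, len(idx), bs):
        batch = idx[start : start + bs]
        xb, yb = X[batch], y[batch]
        logits = net.forward(xb, train=True)
        loss, gl = nn.cross_entropy(logits, yb)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at samples {batch.tolist()}: {loss}"
            )
        net.backward(gl)
        opt.step(net.grads)
        losses.append(loss)
        correct += int((np.argmax(logits, axis=1) == yb).sum())
    return float(np.mean(losses)), correct / len(idx)


def _eval(
    net: nn.Sequential, X: np.ndarray, y: np.ndarray, bs: int
) -> tuple[float, float, tuple[int, int, int, int]]:
    losses, preds = [], []
    for start in range(0, len(X), bs):
        xb, yb = X[start : start + bs], y[start : start + bs]
        logits = net.forward(xb, train=False)
        loss, _ = nn.cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        preds.append(np.argmax(logits, axis=1))
    p = np.concatenate(preds)
    tp = int(((p == 1) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    return float(np.sum(losses) / len(X)), (tp + tn) / len(X), (tp, tn, fp, fn)


def train(
    model: ECNNModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: ECNNConfig | None = None,
    warmup_frac: float = 0.2,
    saliency_refresh: int = 2,
) -> TrainReport:
    """Train the two-pass classifier with mini-batch gradient descent.

    The first ``warmup_frac`` of the epochs trains pass 1 (raw feature
    stacks) only; afterwards the fused saliency maps of the training set are
    generated with the current weights, cached, refreshed every
    ``saliency_refresh`` epochs, and pass 2 is trained on them alongside
    pass 1.  Validation metrics are the pass-2 metrics once saliency
    training has begun, pass-1 metrics before that.  Deterministic for a
    fixed config seed.
    """
    cfg = cfg or model.cfg
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation splits must be non-empty")
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if set(np.unique(y_train)) - {0, 1}:
        raise ValueError("labels must be binary (0=benign, 1=malignant)")

    shuffle_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5F0)))
    opt1 = nn.SGD(model.pass1.params, lr=cfg.learning_rate)
    opt2 = nn.SGD(model.pass2.params, lr=cfg.learning_rate)

    warmup = max(1, int(np.ceil(warmup_frac * cfg.epochs)))
    report = TrainReport([], [], [], [], [], cfg.seed, dataclasses.asdict(cfg))
    oh_cache: np.ndarray | None = None
    val_oh: np.ndarray | None = None

    for epoch in range(cfg.epochs):
        idx = shuffle_rng.permutation(len(X_train))
        loss1, acc1 = _epoch_pass(model, X_train, y_train, idx, opt1, "stack")
        if epoch >= warmup:
            if oh_cache is None or (epoch - warmup) % saliency_refresh == 0:
                oh_cache = np.stack([_fused_map(model, x) for x in X_train])[:, None]
                val_oh = np.stack([_fused_map(model, x) for x in X_val])[:, None]
            loss2, acc2 = _epoch_pass(model, oh_cache, y_train, idx, opt2, "saliency")
            vloss, vacc, vconf = _eval(model.pass2, val_oh, y_val, cfg.batch_size)
            report.train_loss.append((loss1 + loss2) / 2)
            report.train_acc.append(acc2)
        else:
            vloss, vacc, vconf = _eval(model.pass1, X_val, y_val, cfg.batch_size)
            report.train_loss.append(loss1)
            report.train_acc.append(acc1)
        report.val_loss.append(vloss)
        report.val_acc.append(vacc)
        report.val_confusion.append(vconf)
        log.info("epoch %d: train loss %.4f, val acc %.3f", epoch, report.train_loss[-1], vacc)

    if cfg.epochs > warmup:
        # final validation with freshly generated saliency maps, so the
        # reported last-epoch metrics match what predict() produces
        val_oh = np.stack([_fused_map(model, x) for x in X_val])[:, None]
        vloss, vacc, vconf = _eval(model.pass2, val_oh, y_val, cfg.batch_size)
        report.val_loss[-1] = vloss
        report.val_acc[-1] = vacc
        report.val_confusion[-1] = vconf
    return report


def predict(model: ECNNModel, stack: np.ndarray) -> tuple[str, float]:
    """Pass-2 prediction for one feature stack: (label, probability).

    An exact probability tie resolves to benign (lower index) with a warning.
    """
    probs, _ = forward_two_pass(model, stack)
    if probs[0] == probs[1]:
        log.warning("probability tie: resolving to %s", LABEL_NAMES[0])
        return LABEL_NAMES[0], float(probs[0])
    j = int(np.argmax(probs))
    return LABEL_NAMES[j], float(probs[j])


def predict_batch(model: ECNNModel, stacks: np.ndarray) -> np.ndarray:
    """Pass-2 predicted class indices for a batch of stacks."""
    out = []
    for x in stacks:
        probs, _ = forward_two_pass(model, x)
        out.append(int(np.argmax(probs)))
    return np.asarray(out, dtype=np.int64)
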