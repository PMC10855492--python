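"""Evaluation protocols: the four metrics, TP-percentage and k-fold splits,
and the end-to-end pipeline runner.

Metrics (malignant = positive class):

* accuracy = (tp + tn) / (tp + tn + fp + fn)
* CSI (critical success index / threat score) = tp / (tp + fp + fn)
* FPR = fp / (fp + tn)
* FNR = fn / (tp + fn)

A zero denominator yields ``None`` (an explicit "undefined" marker) rather
than 0, so degenerate confusion tables cannot silently inflate results.

"TP" in the split protocol means *training percentage*: TP 80 is an 80/20
stratified hold-out.  Both protocols are seeded and stratified by default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecnn as ecnn_mod
from . import preprocess as pp
from . import synthetic as syn
from .features import extract_features

log = logging.getLogger("gbsd.evalkit")

POSITIVE_LABEL = "malignant"


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class SplitSpec:
    """Evaluation-split specification: TP hold-out or stratified k-fold."""

    mode: str = "tp_percent"  # or "kfold"
    tp: float = 80.0
    k: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("tp_percent", "kfold"):
            raise ValueError("mode must be 'tp_percent' or 'kfold'")
        if not 0 < self.tp < 100:
            raise ValueError("tp must be in (0, 100)")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts for binary labels (malignant positive).

    Accepts label strings or {0, 1} indices.
    """
    yt = _as_binary(y_true)
    yp = _as_binary(y_pred)
    if len(yt) != len(yp):
        raise ValueError(f"length mismatch: {len(yt)} true vs {len(yp)} predicted")
    return ConfusionCounts(
        tp=int(((yp == 1) & (yt == 1)).sum()),
        tn=int(((yp == 0) & (yt == 0)).sum()),
        fp=int(((yp == 1) & (yt == 0)).sum()),
        fn=int(((yp == 0) & (yt == 1)).sum()),
    )


def _as_binary(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "UO":
        bad = set(arr.tolist()) - set(syn.LABELS)
        if bad:
            raise ValueError(f"unknown labels: {bad}")
        return (arr == POSITIVE_LABEL).astype(np.int64)
    uniq = set(np.unique(arr).tolist())
    if bad := uniq - {0, 1}:
        raise ValueError(f"labels must be binary, got {bad}")
    return arr.astype(np.int64)


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, CSI, FPR, FNR; zero denominators yield ``None``."""
    if c.total == 0:
        raise ValueError("metrics require at least one evaluated sample")

    def frac(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return {
        "accuracy": frac(c.tp + c.tn, c.total),
        "csi": frac(c.tp, c.tp + c.fp + c.fn),
        "fpr": frac(c.fp, c.fp + c.tn),
        "fnr": frac(c.fn, c.tp + c.fn),
    }


def tp_split(manifest: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified seeded hold-out at ``spec.tp`` percent training.

    Returns disjoint, exhaustive (train, test) manifests.
    """
    if spec.mode != "tp_percent":
        raise ValueError("spec.mode must be 'tp_percent'")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    groups = manifest.groupby("label").indices if spec.stratified else {"all": np.arange(len(manifest))}
    for label, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
        idx = np.sort(np.asarray(idx))
        perm = rng.permutation(len(idx))
        n_train = int(round(spec.tp / 100 * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train_idx.extend(idx[perm[:n_train]].tolist())
    mask = np.zeros(len(manifest), dtype=bool)
    mask[train_idx] = True
    return manifest[mask].reset_index(drop=True), manifest[~mask].reset_index(drop=True)


def kfold_split(manifest: pd.DataFrame, spec: SplitSpec) -> np.ndarray:
    """Stratified fold assignment: array of fold ids in [0, k)."""
    if spec.mode != "kfold":
        raise ValueError("spec.mode must be 'kfold'")
    n = len(manifest)
    if n < spec.k:
        raise ValueError(f"cannot make {spec.k} folds from {n} samples")
    rng = np.random.default_rng(spec.seed)
    folds = np.empty(n, dtype=np.int64)
    groups = manifest.groupby("label").indices if spec.stratified else {"all": np.arange(n)}
    for _, idx in groups.items():
        idx = np.sort(np.asarray(idx))
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % spec.k
    return folds


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """One end-to-end evaluation run on synthetic data."""

    synthetic: syn.SyntheticConfig = dataclasses.field(default_factory=syn.SyntheticConfig)
    split: SplitSpec = dataclasses.field(default_factory=SplitSpec)
    classifier: ecnn_mod.ECNNConfig = dataclasses.field(default_factory=ecnn_mod.ECNNConfig)
    backbone: str = "small_cnn"
    deep_k: int = 8


def compute_stacks(records: list[syn.ImageRecord], backbone: str = "small_cnn", deep_k: int = 8):
    """Preprocess + featurize a list of image records.

    Returns (stacks array (n, C, 128, 128), label indices, roi results).
    """
    stacks, labels, rois = [], [], []
    for rec in records:
        roi = pp.preprocess_image(rec.pixels)
        fs = extract_features(roi.roi, backbone=backbone, k=deep_k)
        stacks.append(fs.data)
        labels.append(syn.LABELS.index(rec.label))
        rois.append(roi)
    return np.stack(stacks), np.asarray(labels, dtype=np.int64), rois


def _fit_and_score(run: RunConfig, X, y, tr_idx, te_idx, seed: int):
    cfg = dataclasses.replace(run.classifier, seed=seed)
    model = ecnn_mod.build_model(cfg, in_channels=X.shape[1])
    report = ecnn_mod.train(model, X[tr_idx], y[tr_idx], X[te_idx], y[te_idx], cfg)
    preds = ecnn_mod.predict_batch(model, X[te_idx])
    conf = confusion(y[te_idx], preds)
    return model, report, preds, conf


def evaluate(run: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline under ``run`` and assemble the report.

    Generates the synthetic dataset, preprocesses and featurizes it, trains
    the classifier per the split protocol, and writes (when ``out_dir`` is
    given) a per-epoch metrics table, a confusion-matrix CSV and the saved
    per-sample predictions.  Stage failures abort cleanly with the stage
    named in the raised error.
    """
    stage = "generate"
    report: dict = {"stages": {}}
    t0 = time.time()
    try:
        records = syn.records_for_manifest(run.synthetic)
        manifest = pd.DataFrame(
            {"id": [r.id for r in records], "label": [r.label for r in records]}
        )
        report["stages"]["generate"] = round(time.time() - t0, 3)

        stage = "features"
        t1 = time.time()
        X, y, _ = compute_stacks(records, run.backbone, run.deep_k)
        report["stages"]["features"] = round(time.time() - t1, 3)

        stage = "train"
        t1 = time.time()
        rows, conf_rows, pred_rows = [], [], []
        if run.split.mode == "tp_percent":
            tr_m, te_m = tp_split(manifest, run.split)
            tr_idx = manifest.index.get_indexer(manifest[manifest.id.isin(tr_m.id)].index)
            te_idx = manifest.index.get_indexer(manifest[manifest.id.isin(te_m.id)].index)
            _, trep, preds, conf = _fit_and_score(run, X, y, tr_idx, te_idx, run.split.seed)
            for e, (tp, tn, fp, fn) in enumerate(trep.val_confusion):
                m = metrics(ConfusionCounts(tp, tn, fp, fn))
                rows.append({"split": "tp_%g" % run.split.tp, "epoch": e, **m})
            conf_rows.append({"split": "tp_%g" % run.split.tp, **dataclasses.asdict(conf)})
            pred_rows += [
                {"id": manifest.id.iloc[i], "true": int(y[i]), "pred": int(p)}
                for i, p in zip(te_idx, preds)
            ]
            final = metrics(conf)
        else:
            folds = kfold_split(manifest, run.split)
            fold_metrics = []
            for f in range(run.split.k):
                te_idx = np.flatnonzero(folds == f)
                tr_idx = np.flatnonzero(folds != f)
                _, trep, preds, conf = _fit_and_score(run, X, y, tr_idx, te_idx, run.split.seed + f)
                m = metrics(conf)
                fold_metrics.append(m)
                rows.append({"split": f"fold_{f}", "epoch": len(trep.val_acc) - 1, **m})
                conf_rows.append({"split": f"fold_{f}", **dataclasses.asdict(conf)})
                pred_rows += [
                    {"id": manifest.id.iloc[i], "true": int(y[i]), "pred": int(p)}
                    for i, p in zip(te_idx, preds)
                ]
            final = {
                k: float(np.mean([m[k] for m in fold_metrics if m[k] is not None]))
                for k in ("accuracy", "csi", "fpr", "fnr")
            }
            rows.append({"split": "mean", "epoch": -1, **final})
        report["stages"]["train"] = round(time.time() - t1, 3)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    report["metrics"] = final
    report["table"] = rows
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        pd.DataFrame(conf_rows).to_csv(out / "confusion.csv", index=False)
        pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def regenerate_metrics(out_dir: str | Path) -> dict:
    """Recompute the final metrics from the saved predictions CSV."""
    preds = pd.read_csv(Path(out_dir) / "predictions.csv")
    conf = confusion(preds["true"].to_numpy(), preds["pred"].to_numpy())
    return metrics(conf)
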