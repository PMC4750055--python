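"""Evaluation metrics and the architecture ablation table.

Accuracy is the fraction of argmax-correct predictions; per-class
average precision is the area under the one-vs-rest precision-recall
curve ranked by class score, and mAP is its mean over classes present
in the dataset.  Mean per-class precision is reported alongside, since
on an evenly distributed test set the two track each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_fscore_support

from .arch import ArchitectureSpec, Network, count_parameters, preset, reduced
from .losses import softmax_probs
from .train import TrainConfig, center_crop, train

__all__ = ["EvalReport", "evaluate", "ablation_table"]


@dataclass
class EvalReport:
    accuracy: float
    precision: np.ndarray       # per class
    recall: np.ndarray          # per class
    average_precision: np.ndarray  # per class; NaN where undefined
    mAP: float
    mean_precision: float
    missing_classes: list = field(default_factory=list)


def evaluate(net: Network, dataset, split: str | None = "val") -> EvalReport:
    """Score a trained network on a labeled dataset split.

    Classes absent from the split have undefined AP; they are flagged in
    ``missing_classes`` and excluded from the mAP mean (with a warning).
    """
    if split is None:
        images, labels = dataset.images, dataset.labels
    else:
        images, labels = dataset.subset(split)
    if len(images) == 0:
        raise ValueError("empty evaluation split")
    k = net.spec.n_classes
    size = min(net.spec.input_size, images.shape[1], images.shape[2])
    views = np.stack([center_crop(img, size) for img in images])
    scores = net.predict(views)
    if net.spec.loss == "softmax":
        scores = softmax_probs(scores)
    pred = scores.argmax(axis=1)
    accuracy = float(np.mean(pred == labels))
    precision, recall, _, _ = precision_recall_fscore_support(
        labels, pred, labels=np.arange(k), zero_division=0.0
    )
    ap = np.full(k, np.nan)
    missing = []
    for c in range(k):
        pos = labels == c
        if not pos.any():
            missing.append(c)
            continue
        ap[c] = average_precision_score(pos, scores[:, c])
    if missing:
        warnings.warn(f"classes {missing} absent from the evaluation split; excluded from mAP")
    m_ap = float(np.nanmean(ap))
    return EvalReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        average_precision=ap,
        mAP=m_ap,
        mean_precision=float(precision[np.isin(np.arange(k), missing, invert=True)].mean()),
        missing_classes=missing,
    )


def ablation_table(
    presets: list,
    dataset,
    config: TrainConfig,
    desk_scale: bool = True,
    input_size: int = 64,
    width_divisor: int = 4,
    fc_width: int = 256,
) -> pd.DataFrame:
    """Train/evaluate each preset and tabulate (type, parameters, accuracy).

    ``parameters`` is the count of the *full-scale* preset; training runs
    at desk scale (reduced input/widths) unless ``desk_scale=False``.
    The same seed is used for every row, so rows differ only in
    architecture.
    """
    if not presets:
        raise ValueError("at least one preset index is required")
    rows = []
    for idx in presets:
        spec = preset(idx)
        n_params = count_parameters(spec)
        run_spec = (
            reduced(spec, input_size=input_size, width_divisor=width_divisor,
                    fc_width=fc_width, n_classes=dataset.n_classes)
            if desk_scale
            else spec
        )
        net, _curves = train(run_spec, dataset, config)
        report = evaluate(net, dataset, split="val")
        rows.append(
            {
                "type": idx,
                "parameters": n_params,
                "val_accuracy": report.accuracy,
                "mAP": report.mAP,
            }
        )
    return pd.DataFrame(rows)
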