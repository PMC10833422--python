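"""Segmentation evaluation: multi-class Dice, categorical cross-entropy,
voxel accuracy and confusion counts.

Per-class Dice is ``2|P_c & T_c| / (|P_c| + |T_c|)``.  The mean Dice is the
unweighted mean over classes present in at least one of the two volumes;
classes absent from both are excluded (0/0), classes absent from exactly one
score 0.  This keeps a never-present class (e.g. shade-off in a 3-class
setup) from diluting the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .volumes import LabelVolume

EPS = 1e-7


def _as_codes(x) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(x, LabelVolume):
        return x.data, x.class_set
    return np.asarray(x), None


@dataclass
class MetricResult:
    dice_per_class: dict
    dice_mean: float
    cross_entropy: float | None
    voxel_accuracy: float


def dice(pred, truth, n_classes: int | None = None) -> tuple[dict, float]:
    """Per-class and mean Dice between two label arrays/volumes."""
    p, p_cls = _as_codes(pred)
    t, t_cls = _as_codes(truth)
    if p.shape != t.shape:
        raise ContractError(f"shape mismatch {p.shape} vs {t.shape}")
    if p_cls is not None and t_cls is not None and p_cls != t_cls:
        raise ContractError("pred and truth class sets differ")
    names = p_cls or t_cls
    if n_classes is None:
        n_classes = len(names) if names else int(max(p.max(initial=0), t.max(initial=0))) + 1
    per_class: dict = {}
    vals = []
    for c in range(n_classes):
        pc = p == c
        tc = t == c
        np_c, nt_c = int(pc.sum()), int(tc.sum())
        key = names[c] if names else c
        if np_c == 0 and nt_c == 0:
            continue  # absent from both: excluded from the mean
        d = 2.0 * int((pc & tc).sum()) / (np_c + nt_c)
        per_class[key] = d
        vals.append(d)
    mean = float(np.mean(vals)) if vals else float("nan")
    return per_class, mean


def voxel_accuracy(pred, truth) -> float:
    p, _ = _as_codes(pred)
    t, _ = _as_codes(truth)
    if p.shape != t.shape:
        raise ContractError(f"shape mismatch {p.shape} vs {t.shape}")
    return float((p == t).mean())


def confusion_counts(pred, truth, n_classes: int) -> np.ndarray:
    """``(n_classes, n_classes)`` matrix with rows = truth, cols = prediction."""
    p, _ = _as_codes(pred)
    t, _ = _as_codes(truth)
    if p.shape != t.shape:
        raise ContractError(f"shape mismatch {p.shape} vs {t.shape}")
    idx = t.astype(np.int64).ravel() * n_classes + p.astype(np.int64).ravel()
    return np.bincount(idx, minlength=n_classes * n_classes).reshape(n_classes, n_classes)


def categorical_cross_entropy(prob: np.ndarray, truth, channel_axis: int = 0) -> float:
    """Mean ``-log p(true class)`` over voxels/pixels.

    ``prob`` carries class probabilities along ``channel_axis`` and must be
    normalized per voxel to within 1e-6; probabilities are clipped at 1e-7
    before the log.
    """
    t, _ = _as_codes(truth)
    prob = np.asarray(prob, dtype=np.float64)
    prob = np.moveaxis(prob, channel_axis, 0)
    if prob.shape[1:] != t.shape:
        raise ContractError(f"probability field shape {prob.shape[1:]} != truth {t.shape}")
    sums = prob.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ContractError("probabilities do not sum to 1 per voxel (atol 1e-6)")
    k = prob.shape[0]
    if t.size and int(t.max()) >= k:
        raise ContractError(f"truth code {int(t.max())} >= {k} classes")
    p_true = np.take_along_axis(prob, t[None].astype(np.int64), axis=0)[0]
    return float(-np.log(np.clip(p_true, EPS, 1.0)).mean())


def evaluate(pred, truth, prob: np.ndarray | None = None) -> MetricResult:
    """Bundle Dice, accuracy and (if a probability field is given) loss."""
    per_class, mean = dice(pred, truth)
    ce = categorical_cross_entropy(prob, truth) if prob is not None else None
    return MetricResult(per_class, mean, ce, voxel_accuracy(pred, truth))
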