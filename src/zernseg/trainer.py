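"""Training protocol: 80/20 splits, augmentation, Adadelta optimization,
early stopping, and the 2 architectures x 5 training sizes x 2 batch sizes
experiment grid.

Training runs for up to ``max_epochs`` epochs (100 by default) and stops
early once the monitored cross-entropy loss has failed to improve the
best-so-far value by more than 0.01 % (relative) for ten consecutive
epochs.  The monitored loss is the validation loss by default; the
training loss can be monitored instead (``monitor='train'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _nn
from .errors import ConfigurationError, ContractError, TrainingError
from .metrics import dice
from .models import ModelConfig, SegModel, _positions, _slice_window, build_model
from .volumes import GrayVolume, GroundTruthSet, LabelVolume

DEFAULT_TRAIN_SIZES = (10, 20, 30, 50, 70)
DEFAULT_BATCH_SIZES = (32, 64)


@dataclass
class SplitPlan:
    train_indices: tuple[int, ...]
    val_indices: tuple[int, ...]


@dataclass
class TrainRun:
    """Record of one model training."""

    architecture: str
    batch_size: int
    train_size: int
    epochs_run: int
    loss_curve: list[float]  # monitored loss per epoch
    train_loss_curve: list[float]
    val_dice_curve: list[float]
    val_dice: float
    val_loss: float
    seed: int

    def row(self) -> dict:
        return {
            "arch": self.architecture,
            "batch": self.batch_size,
            "train_size": self.train_size,
            "epochs": self.epochs_run,
            "val_dice": self.val_dice,
            "val_loss": self.val_loss,
            "seed": self.seed,
        }


def make_split(gt: GroundTruthSet, seed: int) -> SplitPlan:
    """Deterministic 80/20 split of the ground-truth slices.

    Validation count is ``round(0.2 n)`` with a floor of 1.
    """
    n = len(gt)
    if n < 5:
        raise ConfigurationError(f"need >= 5 ground-truth slices for a split, got {n}")
    n_val = max(1, int(round(0.2 * n)))
    order = np.random.default_rng(seed).permutation(n)
    return SplitPlan(tuple(sorted(order[n_val:])), tuple(sorted(order[:n_val])))


def augment(gray: np.ndarray, label: np.ndarray, rng: np.random.Generator):
    """Random lossless geometric augmentation (90-degree rotations + flips).

    The identical transform is applied to both arrays, so the multiset of
    label classes is preserved exactly.  For slice-context windows the
    transform acts on the trailing two (y, x) axes of ``gray``.
    """
    if gray.shape[-2:] != label.shape[-2:]:
        raise ContractError("gray and label slices differ in y/x shape")
    k = int(rng.integers(4))
    gray = np.rot90(gray, k, axes=(-2, -1))
    label = np.rot90(label, k, axes=(-2, -1))
    if rng.integers(2):
        gray = np.flip(gray, axis=-1)
        label = np.flip(label, axis=-1)
    if rng.integers(2):
        gray = np.flip(gray, axis=-2)
        label = np.flip(label, axis=-2)
    return np.ascontiguousarray(gray), np.ascontiguousarray(label)


def early_stop_check(
    loss_curve, patience: int = 10, rel_tol: float = 1e-4, max_epochs: int = 100
) -> bool:
    """Pure stopping rule on a loss curve.

    True iff each of the last ``patience`` epochs improved the running best
    loss by at most ``rel_tol`` (relative; 0.01 % by default), or the curve
    has reached ``max_epochs``.
    """
    curve = list(loss_curve)
    if not curve:
        raise ContractError("loss curve must contain at least one epoch")
    if len(curve) >= max_epochs:
        return True
    if len(curve) <= patience:
        return False
    streak = 0
    best = curve[0]
    for loss in curve[1:]:
        improvement = (best - loss) / abs(best) if best != 0 else 0.0
        if improvement <= rel_tol:
            streak += 1
        else:
            streak = 0
        best = min(best, loss)
    return streak >= patience


# ---------------------------------------------------------------------------
# patch sampling
# ---------------------------------------------------------------------------

def _patch_grid(shape_yx, patch):
    return [(y0, x0) for y0 in _positions(shape_yx[0], patch) for x0 in _positions(shape_yx[1], patch)]


def _gather_patches(model_cfg: ModelConfig, gt: GroundTruthSet, indices, volume: GrayVolume | None):
    """All (input, label) patch pairs from the given gt slice positions.

    For the slice-context architecture, neighbouring gray slices are taken
    from ``volume`` when provided; otherwise the labeled slice is
    replicated across the window.
    """
    P = model_cfg.patch_size_vox
    xs, ys = [], []
    for i in indices:
        g2, l2 = gt.gray[i], gt.labels[i]
        if model_cfg.architecture == "sensor3d":
            if volume is not None:
                g_in = _slice_window(volume.data, gt.slice_indices[i], model_cfg.context_slices)
            else:
                g_in = np.repeat(g2[None], model_cfg.context_slices, axis=0)
        else:
            g_in = g2[None]
        for y0, x0 in _patch_grid(g2.shape, P):
            xs.append(g_in[:, y0 : y0 + P, x0 : x0 + P])
            ys.append(l2[y0 : y0 + P, x0 : x0 + P])
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.int64)


def _forward_batch(model: SegModel, xb):
    if model.config.architecture == "unet2d":
        xb = xb[:, 0][..., None]
    return model.net.forward(xb)


def _eval_patches(model: SegModel, xp, yp, batch: int = 32):
    """Loss / Dice / accuracy of a model on a fixed patch set (no grads)."""
    losses, preds = [], []
    for i in range(0, len(xp), batch):
        logits, _ = _forward_batch(model, xp[i : i + batch])
        loss, _, prob = _nn.softmax_cross_entropy(logits, yp[i : i + batch])
        losses.append(loss * len(logits))
        preds.append(prob.argmax(axis=-1))
    pred = np.concatenate(preds)
    _, mean_dice = dice(pred, yp, n_classes=model.config.n_classes)
    return float(np.sum(losses) / len(xp)), mean_dice


def train(
    model: SegModel,
    gt: GroundTruthSet,
    batch_size: int,
    seed: int,
    volume: GrayVolume | None = None,
    max_epochs: int = 100,
    patience: int = 10,
    rel_tol: float = 1e-4,
    monitor: str = "val",
    use_augment: bool = True,
    class_weights=None,
) -> TrainRun:
    """Train a model on a ground-truth set; returns the training record.

    Patches tile every training slice with 50 % overlap and are reshuffled
    each epoch with the run seed.  Cross-entropy is unweighted by default;
    ``class_weights='balanced'`` applies inverse-frequency weights computed
    from the training labels (capped at 50), which is useful when a class
    (the LCN) occupies well under a percent of the pixels.  The monitored
    and reported losses are always the plain unweighted cross-entropy.
    """
    if monitor not in ("val", "train"):
        raise ConfigurationError("monitor: must be 'val' or 'train'")
    split = make_split(gt, seed)
    xt, yt = _gather_patches(model.config, gt, split.train_indices, volume)
    xv, yv = _gather_patches(model.config, gt, split.val_indices, volume)
    if isinstance(class_weights, str):
        if class_weights != "balanced":
            raise ConfigurationError("class_weights: expected None, 'balanced' or a vector")
        counts = np.bincount(yt.ravel(), minlength=model.config.n_classes).astype(float)
        class_weights = yt.size / (model.config.n_classes * np.maximum(counts, 1.0))
        class_weights = np.minimum(class_weights, 50.0)
    rng = np.random.default_rng([seed, 0x7E])
    opt = _nn.Adadelta(model.params())

    monitored, train_losses, val_dices = [], [], []
    best = (np.inf, None, float("nan"), float("nan"))  # loss, weights, dice, loss@best
    epoch = 0
    while True:
        epoch += 1
        order = rng.permutation(len(xt))
        ep_losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            xb, yb = xt[idx], yt[idx]
            if use_augment:
                xb, yb = zip(*(augment(a, b, rng) for a, b in zip(xb, yb)))
                xb, yb = np.stack(xb), np.stack(yb)
            opt.zero_grad()
            logits, cache = _forward_batch(model, xb)
            loss, dlogits, _ = _nn.softmax_cross_entropy(logits, yb, class_weights)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            model.net.backward(dlogits, cache)
            opt.step()
            ep_losses.append(loss)
        train_loss = float(np.mean(ep_losses))
        val_loss, val_dice = _eval_patches(model, xv, yv)
        train_losses.append(train_loss)
        val_dices.append(val_dice)
        mon = val_loss if monitor == "val" else train_loss
        monitored.append(mon)
        if mon < best[0]:
            best = (mon, [p.value.copy() for p in model.params()], val_dice, val_loss)
        if early_stop_check(monitored, patience, rel_tol, max_epochs):
            break
    # restore the weights of the best monitored epoch (early stopping with
    # checkpoint restore); reported validation metrics refer to that epoch
    if best[1] is not None:
        for p, v in zip(model.params(), best[1]):
            p.value = v
        val_dice, val_loss = best[2], best[3]
    model.trained_epochs += epoch
    return TrainRun(
        architecture=model.config.architecture,
        batch_size=batch_size,
        train_size=len(gt),
        epochs_run=epoch,
        loss_curve=monitored,
        train_loss_curve=train_losses,
        val_dice_curve=val_dices,
        val_dice=val_dice,
        val_loss=val_loss,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

def evenly_spaced_indices(nz: int, n: int) -> tuple[int, ...]:
    """n unique z-indices evenly covering [0, nz)."""
    return tuple(np.unique(np.linspace(0, nz - 1, n).round().astype(int)))


def ground_truth_from_labels(
    volume: GrayVolume, labels: LabelVolume, n: int, stage: int = 1
) -> GroundTruthSet:
    """Oracle ground truth: n evenly spaced labeled slices from a volume."""
    idx = evenly_spaced_indices(volume.shape[0], n)
    if len(idx) < n:
        raise ConfigurationError(f"volume has too few slices for {n} unique ground-truth slices")
    return GroundTruthSet(
        slice_indices=idx,
        gray=[volume.data[i] for i in idx],
        labels=[labels.data[i] for i in idx],
        stage=stage,
    )


def run_grid(
    volume: GrayVolume,
    gt_sets: dict[int, GroundTruthSet],
    architectures=("unet2d", "sensor3d"),
    train_sizes=DEFAULT_TRAIN_SIZES,
    batch_sizes=DEFAULT_BATCH_SIZES,
    seed: int = 0,
    model_kwargs: dict | None = None,
    **train_kwargs,
) -> list[TrainRun]:
    """Train every (architecture, train size, batch size) grid cell.

    With both architectures and the default five sizes and two batch sizes
    this produces 10 runs per architecture, 20 in total.
    """
    for size in train_sizes:
        if size not in gt_sets:
            raise ConfigurationError(f"missing ground-truth set for train size {size}")
    runs = []
    for arch in architectures:
        for size in train_sizes:
            for batch in batch_sizes:
                cfg = ModelConfig(architecture=arch, seed=seed, **(model_kwargs or {}))
                model = build_model(cfg)
                runs.append(
                    train(model, gt_sets[size], batch, seed=seed, volume=volume, **train_kwargs)
                )
    return runs


def grid_table(runs: list[TrainRun]) -> pd.DataFrame:
    """Tabulate runs as the grid_results table (one row per run)."""
    return pd.DataFrame([r.row() for r in runs])
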