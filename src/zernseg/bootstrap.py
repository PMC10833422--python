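"""Incremental ground-truth generation (bootstrapping) and transfer learning.

The bootstrap mimics the staged labeling workflow used to build training
data for volumetric segmentation: a small cohort of slices is labeled
manually (stage 1), a slice-context model trained on it pre-segments a
larger cohort, a corrector fixes its mistakes, and the enlarged
ground-truth set trains the next stage's models.  Here the human corrector
is simulated by an oracle with access to the phantom's true labels;
``oracle_partial(p)`` models an imperfect corrector that fixes each
mislabeled connected region independently with probability ``p``.

Transfer learning re-dimensions a trained model's classification head for
a (possibly merged) target class set, keeps all other weights, and
retrains on a small target ground-truth set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ContractError
from .models import CLASS_SETS, ModelConfig, SegModel, build_model, predict_slice_probs
from .trainer import TrainRun, evenly_spaced_indices, train
from .volumes import GrayVolume, GroundTruthSet, LabelVolume


@dataclass
class StagePlan:
    """Staged ground-truth growth: cohort sizes and the corrector model."""

    sizes: tuple[int, ...] = (20, 50, 70)
    corrector: str = "oracle_full"  # or "oracle_partial"
    correction_prob: float = 1.0
    intermediate_arch: str = "sensor3d"
    include_previous: bool = True  # later cohorts are supersets of earlier ones

    def validate(self) -> None:
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ConfigurationError(f"sizes: stage sizes must be strictly increasing, got {self.sizes}")
        if self.corrector not in ("oracle_full", "oracle_partial"):
            raise ConfigurationError(f"corrector: unknown '{self.corrector}'")
        if not 0.0 <= self.correction_prob <= 1.0:
            raise ConfigurationError("correction_prob: must lie in [0, 1]")


@dataclass
class TransferPlan:
    """Head remapping for transfer to a (possibly merged) class set."""

    class_remap: dict = field(
        default_factory=lambda: {"background": "background", "bone": "bone",
                                 "shade_off": "bone", "lcn": "lcn"}
    )
    target_gt_count: int = 20


@dataclass
class StageResult:
    stage: int
    gt: GroundTruthSet
    models: dict  # arch -> SegModel
    runs: dict  # arch -> TrainRun
    corrections: int


@dataclass
class BootstrapResult:
    stages: list[StageResult]

    @property
    def final_models(self) -> dict:
        return self.stages[-1].models


def simulate_correction(
    pred: list[np.ndarray],
    truth: list[np.ndarray],
    corrector: str = "oracle_full",
    correction_prob: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], int]:
    """Simulated manual correction of predicted label slices.

    ``oracle_full`` replaces every mislabeled region with the truth;
    ``oracle_partial`` corrects each mislabeled connected region (2D,
    8-connectivity) independently with probability ``correction_prob``.
    Returns the corrected slices and the number of corrected regions.
    """
    if len(pred) != len(truth):
        raise ContractError("pred and truth slice counts differ")
    rng = rng or np.random.default_rng(0)
    corrected, n_corr = [], 0
    for p2, t2 in zip(pred, truth):
        if p2.shape != t2.shape:
            raise ContractError("pred and truth slice shapes differ")
        if corrector == "oracle_full":
            n_corr += int(ndimage.label(p2 != t2, structure=np.ones((3, 3)))[1])
            corrected.append(t2.copy())
            continue
        wrong = p2 != t2
        comp, n = ndimage.label(wrong, structure=np.ones((3, 3)))
        out = p2.copy()
        for ci in range(1, n + 1):
            if rng.random() < correction_prob:
                m = comp == ci
                out[m] = t2[m]
                n_corr += 1
        corrected.append(out)
    return corrected, n_corr


def calibrate_volume_fraction(
    model: SegModel,
    volume: GrayVolume,
    gt: GroundTruthSet,
    class_name: str = "lcn",
) -> float:
    """Match the model's predicted voxel fraction of one class to the
    labeled ground-truth cohort.

    Segmentation-derived volume fractions (porosity) are sensitive to a
    model's class prior, which class-weighted training shifts.  This fits a
    single additive logit offset for ``class_name`` (by bisection on the
    labeled slices) so that the predicted voxel count of that class on the
    ground-truth cohort equals the labeled count, stores it on the model
    (``class_logit_bias``), and returns the offset.  Deterministic; uses
    only the labeled slices an annotator would have.
    """
    names = model.class_set
    if class_name not in names:
        raise ConfigurationError(f"class '{class_name}' not in model class set {names}")
    c = names.index(class_name)
    model.class_logit_bias = None
    probs = np.stack([predict_slice_probs(model, volume.data, i) for i in gt.slice_indices])
    code_counts = sum(int((l2 == c).sum()) for l2 in gt.labels)
    logp = np.log(np.clip(probs, 1e-12, 1.0))  # (n, K, Y, X)

    def count(delta: float) -> int:
        adj = logp.copy()
        adj[:, c] += delta
        return int((adj.argmax(axis=1) == c).sum())

    lo, hi = -6.0, 6.0
    if count(lo) > code_counts or count(hi) < code_counts:
        delta = 0.0  # out of range: leave the model unadjusted
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if count(mid) < code_counts:
                lo = mid
            else:
                hi = mid
        delta = 0.5 * (lo + hi)
    bias = np.zeros(len(names), dtype=np.float64)
    bias[c] = delta
    model.class_logit_bias = bias
    return delta


def _gt_from(volume: GrayVolume, indices, labels_2d, stage: int) -> GroundTruthSet:
    return GroundTruthSet(
        slice_indices=tuple(indices),
        gray=[volume.data[i] for i in indices],
        labels=list(labels_2d),
        stage=stage,
    )


def run_bootstrap(
    volume: GrayVolume,
    labels: LabelVolume,
    plan: StagePlan,
    model_config: ModelConfig,
    seed: int,
    architectures: tuple[str, ...] = ("sensor3d", "unet2d"),
    **train_kwargs,
) -> BootstrapResult:
    """Run the staged ground-truth bootstrap on a labeled volume.

    Stage 1 trains on ``plan.sizes[0]`` oracle-labeled slices.  Each later
    stage segments its (evenly spaced) slice cohort with the previous
    stage's intermediate model, applies the simulated corrector, and
    retrains every architecture on the enlarged ground-truth set.

    ``train_kwargs`` are forwarded to :func:`zernseg.trainer.train`;
    phantom-scale runs default to balanced class weights so the sparse LCN
    class is learned within a small epoch budget.
    """
    plan.validate()
    nz = volume.shape[0]
    if plan.sizes[-1] > nz:
        raise ConfigurationError(f"sizes: largest stage {plan.sizes[-1]} exceeds {nz} slices")
    calibrate = train_kwargs.pop("calibrate_lcn", True)
    train_kwargs.setdefault("class_weights", "balanced")
    rng = np.random.default_rng([seed, 0xB0])
    batch_size = train_kwargs.pop("batch_size", 32)

    stages: list[StageResult] = []
    prev_model: SegModel | None = None
    prev_gt: GroundTruthSet | None = None
    for k, size in enumerate(plan.sizes, start=1):
        if k == 1:
            idx = evenly_spaced_indices(nz, size)
            slice_labels = [labels.data[i] for i in idx]
            n_corr = 0
        else:
            known = dict(zip(prev_gt.slice_indices, prev_gt.labels)) if plan.include_previous else {}
            # enlarge to `size` slices: keep the previous cohort and add evenly
            # spaced new slices from the remainder of the stack
            candidates = [i for i in range(nz) if i not in known]
            n_new = size - len(known)
            pick = np.unique(np.linspace(0, len(candidates) - 1, n_new).round().astype(int))
            new_idx = [candidates[i] for i in pick]
            pred = [
                predict_slice_probs(prev_model, volume.data, i).argmax(axis=0).astype(np.uint8)
                for i in new_idx
            ]
            truth = [labels.data[i] for i in new_idx]
            corrected, n_corr = simulate_correction(
                pred, truth, plan.corrector, plan.correction_prob, rng
            )
            merged = dict(zip(new_idx, corrected))
            merged.update(known)
            idx = tuple(sorted(merged))
            slice_labels = [merged[i] for i in idx]
        gt = _gt_from(volume, idx, slice_labels, stage=k)

        models, runs = {}, {}
        from dataclasses import replace as _replace

        for arch in architectures:
            cfg = _replace(model_config, architecture=arch)
            model = build_model(cfg)
            runs[arch] = train(model, gt, batch_size, seed=seed, volume=volume, **train_kwargs)
            if calibrate and "lcn" in model.class_set:
                calibrate_volume_fraction(model, volume, gt, "lcn")
            models[arch] = model
        stages.append(StageResult(stage=k, gt=gt, models=models, runs=runs, corrections=n_corr))
        prev_model = models[plan.intermediate_arch if plan.intermediate_arch in models else architectures[0]]
        prev_gt = gt
    return BootstrapResult(stages=stages)


# ---------------------------------------------------------------------------
# transfer learning
# ---------------------------------------------------------------------------

def remap_class_set(remap: dict) -> tuple[str, ...]:
    """Ordered target class set implied by a source->target remap."""
    order = ("background", "bone", "shade_off", "lcn")
    seen = []
    for name in order:
        t = remap.get(name)
        if t is not None and t not in seen:
            seen.append(t)
    return tuple(seen)


def transfer_learn(
    source: SegModel,
    target_gt: GroundTruthSet,
    plan: TransferPlan,
    seed: int,
    volume: GrayVolume | None = None,
    batch_size: int = 32,
    **train_kwargs,
) -> tuple[SegModel, TrainRun | None]:
    """Fine-tune a trained model on a new (possibly 3-class) domain.

    The classification head is re-dimensioned for the target class set
    (merged classes sum their head weights as a warm start); all other
    weights are initialized from the source model.  With ``max_epochs=0``
    no retraining happens and the returned model's probabilities equal the
    source model's probabilities with the class remap applied (merged
    classes sum their probabilities), so its predictions are exactly the
    source model's remapped predictions.
    """
    src_classes = CLASS_SETS[source.config.n_classes]
    for name in src_classes:
        if name not in plan.class_remap:
            raise ConfigurationError(f"class_remap: missing source class '{name}'")
    target_set = remap_class_set({k: v for k, v in plan.class_remap.items() if k in src_classes})
    n_target = len(target_set)
    if target_set != CLASS_SETS.get(n_target):
        raise ConfigurationError(f"class_remap: unsupported target class set {target_set}")
    groups = [
        [i for i, s in enumerate(src_classes) if plan.class_remap[s] == t] for t in target_set
    ]

    from dataclasses import replace as _replace

    cfg = _replace(source.config, n_classes=n_target, seed=seed)
    max_epochs = train_kwargs.get("max_epochs", 100)
    if max_epochs == 0:
        frozen = SegModel(config=cfg, net=_ProbMergeNet(source.net, groups),
                          trained_epochs=source.trained_epochs)
        return frozen, None

    model = build_model(cfg)
    src_params = source.params()
    dst_params = model.params()
    # all layers except the head (last conv: weight + bias) match in shape
    for ps, pd in zip(src_params[:-2], dst_params[:-2]):
        if ps.value.shape != pd.value.shape:
            raise ConfigurationError("source and target architectures are incompatible")
        pd.value = ps.value.copy()
    w_src, b_src = src_params[-2].value, src_params[-1].value
    for t, grp in enumerate(groups):
        dst_params[-2].value[..., t] = w_src[..., grp].sum(axis=-1)
        dst_params[-1].value[t] = b_src[grp].sum()
    model.trained_epochs = source.trained_epochs
    run = train(model, target_gt, batch_size, seed=seed, volume=volume, **train_kwargs)
    return model, run


class _ProbMergeNet:
    """Inference-only wrapper: source probabilities summed per class group.

    Emits ``log(sum of group probabilities)`` so that a downstream softmax
    reproduces the merged probabilities exactly.
    """

    def __init__(self, net, groups):
        self._net = net
        self._groups = groups

    def params(self):
        return self._net.params()

    def forward(self, x):
        from ._nn import softmax

        logits, _ = self._net.forward(x)
        p = softmax(logits, axis=-1)
        merged = np.stack([p[..., g].sum(axis=-1) for g in self._groups], axis=-1)
        return np.log(np.clip(merged, 1e-30, 1.0)), None

    def backward(self, dlogits, cache):  # pragma: no cover - inference only
        raise ContractError("a 0-epoch transferred model cannot be trained further")
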