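"""Segmentation model architectures behind a common contract.

Two architectures are provided:

``unet2d``
    A standard 2D encoder-decoder with skip connections: two 3x3
    convolutions per level, channel doubling, 2x2 max-pool down,
    2x2 transposed-convolution up, and a 1x1 softmax head.

``sensor3d``
    A slice-context ("2.5D") variant: the same 2D encoder is applied with
    *shared weights* to each slice of an ordered window of
    ``context_slices`` neighbouring slices; the per-slice bottleneck
    features are merged by a learned 1x1 slice-mixing convolution, and a
    decoder (with skip connections from the centre slice) predicts the
    centre slice.  This gives the model access to inter-slice correlations
    at modest memory cost.

Both consume gray patches in ``[0, 1]`` and emit per-class probability
maps.  Initialization is deterministic for a fixed config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Adadelta, Conv2D, ConvTranspose2, MaxPool2, ReLU  # noqa: F401
from .errors import ConfigurationError, ContractError
from .volumes import CLASSES, GrayVolume, LabelVolume

CLASS_SETS = {
    2: ("background", "bone"),
    3: ("background", "bone", "lcn"),
    4: CLASSES,
}


@dataclass
class ModelConfig:
    architecture: str = "sensor3d"
    n_classes: int = 4
    depth: int = 2
    base_channels: int = 8
    context_slices: int = 3
    patch_size_vox: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ("unet2d", "sensor3d"):
            raise ConfigurationError(f"architecture: unknown '{self.architecture}'")
        if self.n_classes not in (2, 3, 4):
            raise ConfigurationError("n_classes: must be 2, 3 or 4")
        if self.patch_size_vox % (2**self.depth) != 0:
            raise ConfigurationError(
                f"patch_size_vox: {self.patch_size_vox} not divisible by 2^depth={2**self.depth}"
            )
        if self.context_slices < 1 or self.context_slices % 2 == 0:
            raise ConfigurationError("context_slices: must be an odd integer >= 1")


class _ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, cin, cout, rng):
        self.c1 = Conv2D(cin, cout, 3, rng)
        self.c2 = Conv2D(cout, cout, 3, rng)
        self.r = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        h1, k1 = self.c1.forward(x)
        a1, m1 = self.r.forward(h1)
        h2, k2 = self.c2.forward(a1)
        a2, m2 = self.r.forward(h2)
        return a2, (k1, m1, k2, m2)

    def backward(self, dy, cache):
        k1, m1, k2, m2 = cache
        d = self.r.backward(dy, m2)
        d = self.c2.backward(d, k2)
        d = self.r.backward(d, m1)
        return self.c1.backward(d, k1)


class _Encoder:
    def __init__(self, cin, base, depth, rng):
        self.blocks = []
        self.pool = MaxPool2()
        c = cin
        for level in range(depth):
            self.blocks.append(_ConvBlock(c, base * 2**level, rng))
            c = base * 2**level
        self.bottleneck = _ConvBlock(c, base * 2**depth, rng)

    def params(self):
        out = []
        for b in self.blocks:
            out += b.params()
        return out + self.bottleneck.params()

    def forward(self, x):
        skips, caches = [], []
        h = x
        for b in self.blocks:
            h, cb = b.forward(h)
            skips.append(h)
            h, cp = self.pool.forward(h)
            caches.append((cb, cp))
        h, cbot = self.bottleneck.forward(h)
        return h, skips, (caches, cbot)


class _Decoder:
    def __init__(self, base, depth, n_classes, rng):
        self.ups, self.blocks = [], []
        for level in reversed(range(depth)):
            c = base * 2**level
            self.ups.append(ConvTranspose2(c * 2, c, rng))
            self.blocks.append(_ConvBlock(c * 2, c, rng))
        self.head = Conv2D(base, n_classes, 1, rng)

    def params(self):
        out = []
        for u, b in zip(self.ups, self.blocks):
            out += u.params() + b.params()
        return out + self.head.params()

    def forward(self, h, skips):
        caches = []
        for u, b, s in zip(self.ups, self.blocks, reversed(skips)):
            h, cu = u.forward(h)
            h = np.concatenate([s, h], axis=-1)
            h, cb = b.forward(h)
            caches.append((cu, cb, s.shape[-1]))
        logits, ch = self.head.forward(h)
        return logits, (caches, ch)

    def backward(self, dlogits, cache):
        caches, ch = cache
        d = self.head.backward(dlogits, ch)
        dskips = []
        for (cu, cb, ns), u, b in zip(reversed(caches), reversed(self.ups), reversed(self.blocks)):
            d = b.backward(d, cb)
            dskips.append(d[..., :ns])
            d = u.backward(d[..., ns:], cu)
        dskips.reverse()  # now ordered shallow -> deep? see note below
        return d, dskips


class UNet2DNet:
    """Single-slice U-Net; input (B, H, W, 1) channels-last."""

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.enc = _Encoder(1, cfg.base_channels, cfg.depth, rng)
        self.dec = _Decoder(cfg.base_channels, cfg.depth, cfg.n_classes, rng)
        self.depth = cfg.depth

    def params(self):
        return self.enc.params() + self.dec.params()

    def forward(self, x):
        h, skips, ce = self.enc.forward(x)
        logits, cd = self.dec.forward(h, skips)
        return logits, (ce, cd)

    def backward(self, dlogits, cache):
        ce, cd = cache
        dh, dskips_deepfirst = self.dec.backward(dlogits, cd)
        # decoder iterates deep -> shallow; after reverse() dskips are
        # ordered shallow-last; encoder wants per-level (shallow..deep)
        dskips = list(reversed(dskips_deepfirst))
        return _encoder_backward(self.enc, dh, dskips, ce)


def _encoder_backward(enc: _Encoder, dh, dskips, cache):
    caches, cbot = cache
    d = enc.bottleneck.backward(dh, cbot)
    for level in reversed(range(len(enc.blocks))):
        cb, cp = caches[level]
        d = enc.pool.backward(d, cp)
        if dskips[level] is not None:
            d = d + dskips[level]
        d = enc.blocks[level].backward(d, cb)
    return d


class Sensor3DNet:
    """Slice-context network; input (B, S, H, W), predicts the centre slice."""

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.enc = _Encoder(1, cfg.base_channels, cfg.depth, rng)
        cb = cfg.base_channels * 2**cfg.depth
        self.mixer = Conv2D(cfg.context_slices * cb, cb, 1, rng)
        self.relu = ReLU()
        self.dec = _Decoder(cfg.base_channels, cfg.depth, cfg.n_classes, rng)
        self.S = cfg.context_slices

    def params(self):
        return self.enc.params() + self.mixer.params() + self.dec.params()

    def forward(self, x):
        B, S, H, W = x.shape
        if S != self.S:
            raise ContractError(f"expected {self.S} context slices, got {S}")
        center = S // 2
        feats, enc_caches, center_skips = [], [], None
        for s in range(S):
            h, skips, ce = self.enc.forward(x[:, s][..., None])
            feats.append(h)
            enc_caches.append(ce)
            if s == center:
                center_skips = skips
        mixed = np.concatenate(feats, axis=-1)
        m, cm = self.mixer.forward(mixed)
        a, cr = self.relu.forward(m)
        logits, cd = self.dec.forward(a, center_skips)
        cb = feats[0].shape[-1]
        return logits, (enc_caches, cm, cr, cd, cb, center)

    def backward(self, dlogits, cache):
        enc_caches, cm, cr, cd, cb, center = cache
        da, dskips_deepfirst = self.dec.backward(dlogits, cd)
        dskips = list(reversed(dskips_deepfirst))
        dm = self.relu.backward(da, cr)
        dmixed = self.mixer.backward(dm, cm)
        none_skips = [None] * len(dskips)
        for s, ce in enumerate(enc_caches):
            dh = dmixed[..., s * cb : (s + 1) * cb]
            _encoder_backward(self.enc, dh, dskips if s == center else none_skips, ce)
        return None


@dataclass
class SegModel:
    """A configured network plus its training state.

    ``class_logit_bias`` is an optional per-class log-prior offset applied
    at prediction time (volume-fraction calibration); ``None`` means no
    adjustment.
    """

    config: ModelConfig
    net: object = field(repr=False, default=None)
    trained_epochs: int = 0
    class_logit_bias: np.ndarray | None = None

    @property
    def class_set(self) -> tuple[str, ...]:
        return CLASS_SETS[self.config.n_classes]

    def params(self):
        return self.net.params()


def build_model(config: ModelConfig) -> SegModel:
    """Instantiate a model with deterministic, seeded initialization."""
    config.validate()
    net = UNet2DNet(config) if config.architecture == "unet2d" else Sensor3DNet(config)
    return SegModel(config=config, net=net)


# ---------------------------------------------------------------------------
# prediction: tiled, overlap-blended inference over a whole volume
# ---------------------------------------------------------------------------

def _positions(dim: int, patch: int) -> list[int]:
    if dim < patch:
        raise ContractError(f"volume extent {dim} smaller than patch {patch} in y/x (tiling)")
    if dim == patch:
        return [0]
    pos = list(range(0, dim - patch + 1, patch // 2))
    if pos[-1] != dim - patch:
        pos.append(dim - patch)
    return pos


def _cosine_window(patch: int) -> np.ndarray:
    w = 0.5 - 0.5 * np.cos(2 * np.pi * (np.arange(patch) + 0.5) / patch)
    w = 0.1 + 0.9 * w  # floor keeps edge tiles contributing
    return np.outer(w, w).astype(np.float32)


def _slice_window(gray: np.ndarray, z: int, s: int) -> np.ndarray:
    """Ordered window of s slices centred on z, reflect-padded in z."""
    half = s // 2
    nz = gray.shape[0]

    def reflect(i: int) -> int:
        if i < 0:
            i = -i
        if i >= nz:
            i = 2 * nz - 2 - i
        return max(0, min(nz - 1, i))

    return gray[[reflect(z + o) for o in range(-half, half + 1)]]


def predict_slice_probs(model: SegModel, gray: np.ndarray, z: int) -> np.ndarray:
    """Per-class probabilities (K, Y, X) for one z-slice of a gray array."""
    cfg = model.config
    P = cfg.patch_size_vox
    Y, X = gray.shape[1:]
    ys, xs = _positions(Y, P), _positions(X, P)
    win = _cosine_window(P)
    if cfg.architecture == "unet2d":
        tiles = np.stack([gray[z, y0 : y0 + P, x0 : x0 + P] for y0 in ys for x0 in xs])[..., None]
    else:
        w = _slice_window(gray, z, cfg.context_slices)
        tiles = np.stack([w[:, y0 : y0 + P, x0 : x0 + P] for y0 in ys for x0 in xs])
    logits, _ = model.net.forward(tiles.astype(np.float32))
    if model.class_logit_bias is not None:
        logits = logits + model.class_logit_bias.astype(np.float32)
    probs = _nn.softmax(logits, axis=-1)
    acc = np.zeros((Y, X, cfg.n_classes), dtype=np.float32)
    wacc = np.zeros((Y, X), dtype=np.float32)
    t = 0
    for y0 in ys:
        for x0 in xs:
            acc[y0 : y0 + P, x0 : x0 + P, :] += probs[t] * win[..., None]
            wacc[y0 : y0 + P, x0 : x0 + P] += win
            t += 1
    return np.moveaxis(acc / wacc[..., None], -1, 0)


def predict_volume(model: SegModel, vol: GrayVolume) -> tuple[np.ndarray, LabelVolume]:
    """Segment a whole volume; returns ``(probs (Z,K,Y,X), LabelVolume)``."""
    gray = vol.data
    probs = np.stack([predict_slice_probs(model, gray, z) for z in range(gray.shape[0])])
    labels = probs.argmax(axis=1).astype(np.uint8)
    return probs, LabelVolume(labels, CLASS_SETS[model.config.n_classes], vol.voxel_size_nm)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegModel, path: str | Path) -> Path:
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    if model.class_logit_bias is not None:
        arrays["_class_logit_bias"] = model.class_logit_bias
    meta = json.dumps({"config": asdict(model.config), "trained_epochs": model.trained_epochs})
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> SegModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        model = build_model(ModelConfig(**meta["config"]))
        for i, p in enumerate(model.params()):
            p.value = data[f"p{i}"].astype(np.float32)
        if "_class_logit_bias" in data:
            model.class_logit_bias = data["_class_logit_bias"]
        model.trained_epochs = meta["trained_epochs"]
    return model
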