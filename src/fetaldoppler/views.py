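"""Dual-encoder convolutional view classifiers (UA vs MCA, AoI vs LVIO).

Each pair classifier fuses two independent residual convolutional encoders
— one for the 256x256 B-mode region, one for the 512-wide spectral Doppler
region — whose pooled features are projected, concatenated into a joint
embedding and passed through a fully connected head ending in 2 logits.
Weights are never shared between the two encoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.layers import (
    Module,
    Conv2d,
    ReLU,
    MaxPool2d,
    Linear,
    GlobalAvgPool,
    Sequential,
    state_dict,
    load_state_dict,
)
from .nn.losses import softmax_cross_entropy

BMODE_INPUT = (256, 256, 1)
DOPPLER_INPUT = (256, 512, 1)

#: classes handled by each gate group's pair model
PAIR_CLASSES = {"UA_MCA": ("UA", "MCA"), "AOI_LVIO": ("AoI", "LVIO")}

#: encoder profiles: (stem width, stem pools, [(width, n_res_blocks)...], proj)
ENCODER_PROFILES = {
    # ~1e5 parameters across both encoders + head: the desk-scale default
    "reduced": dict(stem=8, stem_pools=2, stages=[(8, 1), (16, 1)], proj=32),
    # full-scale residual encoder in the 50-layer class; projection to 1024
    # per branch so the concatenated embedding is 2048
    "full": dict(stem=64, stem_pools=2, stages=[(64, 3), (128, 4), (256, 6), (512, 3)], proj=1024),
}


@dataclass
class DualEncoderSpec:
    """Architecture descriptor for a pair classifier."""

    pair: str
    encoder_profile: str = "reduced"
    bmode_input: tuple = BMODE_INPUT
    doppler_input: tuple = DOPPLER_INPUT
    share_weights: bool = False  # fixed: independent encoders

    @property
    def proj_dim(self) -> int:
        return ENCODER_PROFILES[self.encoder_profile]["proj"]

    @property
    def head_sizes(self) -> tuple[int, int, int]:
        """Fully connected head layer sizes (input embedding, hidden, 2)."""
        p2 = 2 * self.proj_dim
        return (p2, max(p2 // 8, 8), 2)


@dataclass
class ViewPrediction:
    label: str
    score: float
    scores: dict


class ResidualBlock(Module):
    """Pre-activation-free basic block: relu(x + conv(relu(conv(x))))."""

    def __init__(self, width: int, rng):
        self.c1 = Conv2d(width, width, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(width, width, 3, rng)
        self.r2 = ReLU()

    def forward(self, x, train: bool = False):
        h = self.c2.forward(self.r1.forward(self.c1.forward(x, train), train), train)
        return self.r2.forward(x + h, train)

    def backward(self, grad):
        g = self.r2.backward(grad)
        gh = self.c1.backward(self.r1.backward(self.c2.backward(g)))
        return g + gh


class ResidualEncoder(Module):
    """Scalable residual CNN: stem, pooled residual stages, pooled features
    projected to a fixed-length embedding."""

    def __init__(self, profile: str, proj_dim: int | None = None, rng=None):
        rng = rng or np.random.default_rng(0)
        cfg = ENCODER_PROFILES[profile]
        self.profile = profile
        mods: list[Module] = [Conv2d(1, cfg["stem"], 3, rng), ReLU()]
        for _ in range(cfg["stem_pools"]):
            mods.append(MaxPool2d())
        w_prev = cfg["stem"]
        for w, n_blocks in cfg["stages"]:
            if w != w_prev:
                mods += [Conv2d(w_prev, w, 3, rng), ReLU()]
            for _ in range(n_blocks):
                mods.append(ResidualBlock(w, rng))
            mods.append(MaxPool2d())
            w_prev = w
        self.body = Sequential(*mods)
        self.gap = GlobalAvgPool()
        self.proj = Linear(w_prev, proj_dim or cfg["proj"], rng)

    def features(self, x, train: bool = False):
        h = self.body.forward(x, train=train)
        h = self.gap.forward(h, train=train)
        return self.proj.forward(h, train=train)

    forward = features

    def backward(self, grad):
        g = self.proj.backward(grad)
        g = self.gap.backward(g)
        return self.body.backward(g)


class DualEncoderModel(Module):
    """(bmode, doppler) -> 2 logits through two independent encoders."""

    def __init__(self, spec: DualEncoderSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.enc_b = ResidualEncoder(spec.encoder_profile, rng=rng)
        self.enc_d = ResidualEncoder(spec.encoder_profile, rng=rng)
        p2, hidden, n_out = spec.head_sizes
        self.head = Sequential(Linear(p2, hidden, rng), ReLU(), Linear(hidden, n_out, rng))
        self._p = spec.proj_dim

    def forward(self, bmode, doppler, train: bool = False):
        if bmode.shape[1:3] != self.spec.bmode_input[:2]:
            raise ValueError(
                f"bmode shape {bmode.shape[1:3]} != expected {self.spec.bmode_input[:2]}"
            )
        if doppler.shape[1:3] != self.spec.doppler_input[:2]:
            raise ValueError(
                f"doppler shape {doppler.shape[1:3]} != expected {self.spec.doppler_input[:2]}"
            )
        fb = self.enc_b.features(bmode, train=train)
        fd = self.enc_d.features(doppler, train=train)
        emb = np.concatenate([fb, fd], axis=1)
        return self.head.forward(emb, train=train)

    def backward(self, dlogits):
        g = self.head.backward(dlogits)
        gb, gd = g[:, : self._p], g[:, self._p :]
        self.enc_b.backward(gb)
        self.enc_d.backward(gd)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param_{i}": a for i, a in enumerate(state_dict(self))}
        np.savez_compressed(
            path,
            pair=self.spec.pair,
            profile=self.spec.encoder_profile,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "DualEncoderModel":
        z = np.load(path, allow_pickle=False)
        spec = DualEncoderSpec(pair=str(z["pair"]), encoder_profile=str(z["profile"]))
        model = cls(spec)
        n = len([k for k in z.files if k.startswith("param_")])
        load_state_dict(model, [z[f"param_{i}"] for i in range(n)])
        return model


def build_dual_encoder(config: DualEncoderSpec | dict, seed: int = 0) -> DualEncoderModel:
    """Instantiate a pair classifier from a spec (or dict of spec fields)."""
    if isinstance(config, dict):
        config = DualEncoderSpec(**config)
    if config.encoder_profile not in ENCODER_PROFILES:
        raise ValueError(
            f"unknown encoder profile {config.encoder_profile!r}; "
            f"expected one of {sorted(ENCODER_PROFILES)}"
        )
    return DualEncoderModel(config, seed=seed)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


@dataclass
class ViewTrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def _as_batch(samples):
    b = np.stack([np.asarray(s[0], dtype=np.float32) for s in samples])[..., None]
    d = np.stack([np.asarray(s[1], dtype=np.float32) for s in samples])[..., None]
    y = np.array([int(s[2]) for s in samples])
    return b, d, y


def train_view_classifier(
    train_set,
    val_set,
    train_config=None,
    pair: str = "UA_MCA",
    augment_fn=None,
):
    """Train one pair classifier on (bmode, doppler, label) triples.

    Cross-entropy loss, Adam at the configured learning rate, with the
    learning rate reduced by the plateau factor after ``patience`` epochs
    without validation-loss improvement; ``augment_fn(bmode, doppler, rng)``
    is applied per sample per epoch when given.  Returns
    ``(model, history)``.
    """
    from .training import TrainConfig

    cfg = train_config or TrainConfig(epochs=20)
    if len(train_set) == 0:
        raise ValueError("empty training set")
    labels = {int(s[2]) for s in train_set}
    if len(labels) < 2:
        raise ValueError(f"training set contains a single class {labels}")
    rng = np.random.default_rng(cfg.seed)
    model = DualEncoderModel(DualEncoderSpec(pair=pair), seed=cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.plateau_factor, patience=cfg.patience)
    hist = ViewTrainHistory()
    vb, vd, vy = _as_batch(val_set) if len(val_set) else (None, None, None)
    for _ in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[start : start + cfg.batch_size]]
            if augment_fn is not None:
                batch = [augment_fn(*s, rng) for s in batch]
            b, d, y = _as_batch(batch)
            logits = model.forward(b, d, train=True)
            loss, dz = softmax_cross_entropy(logits, y)
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        hist.train_loss.append(float(np.mean(losses)))
        if vb is not None:
            vloss, _ = softmax_cross_entropy(model.forward(vb, vd), vy)
        else:
            vloss = hist.train_loss[-1]
        hist.val_loss.append(float(vloss))
        hist.lr.append(opt.lr)
        sched.step(vloss)
    return model, hist


def predict_view(model: DualEncoderModel, bmode: np.ndarray, doppler: np.ndarray) -> ViewPrediction:
    """Softmax prediction of one study's view within the model's pair."""
    classes = PAIR_CLASSES[model.spec.pair]
    b = np.asarray(bmode, dtype=np.float32)[None, :, :, None]
    d = np.asarray(doppler, dtype=np.float32)[None, :, :, None]
    logits = model.forward(b, d)[0]
    z = logits - logits.max()
    p = np.exp(z) / np.exp(z).sum()
    i = int(np.argmax(p))
    return ViewPrediction(
        label=classes[i],
        score=float(p[i]),
        scores={c: float(s) for c, s in zip(classes, p)},
    )


def classifier_accuracy(model, samples) -> float:
    """Fraction of (bmode, doppler, label) samples classified correctly."""
    b, d, y = _as_batch(samples)
    logits = model.forward(b, d)
    return float(np.mean(np.argmax(logits, axis=1) == y))
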