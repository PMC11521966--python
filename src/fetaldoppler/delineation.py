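"""Per-view W-Net waveform delineation.

A W-Net — two stacked U-shaped encoder–decoder networks, with skip
connections from the first decoder into the second encoder to avoid a
bottleneck between the two U-Nets — maps a 512x256 spectrogram to an
(M+1)-channel mask: channel 0 is the velocity-envelope region, channels
1..M locate each physiological event type in time as narrow column bands.
M is 2 for UA, MCA and AoI (onset S, S peak) and 7 for LVIO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.layers import Module, Conv2d, ReLU, MaxPool2d, Upsample2d
from .nn.losses import sigmoid, dice_f1_loss, bce_loss
from .synthetic import EVENT_VOCAB, ALL_VIEWS

DOPPLER_SHAPE = (256, 512)

#: default half-width (columns) of an encoded event band
EVENT_BAND_HALFWIDTH = 2
#: default half-height (rows) of an encoded event band around the envelope row
EVENT_BAND_HALFHEIGHT = 4


def n_event_channels(view: str) -> int:
    if view not in EVENT_VOCAB:
        raise ValueError(f"unknown view {view!r}")
    return len(EVENT_VOCAB[view])


@dataclass
class DelineationMask:
    """(M+1)-channel binary raster: envelope + one channel per event type."""

    view: str
    channels: np.ndarray  # (M+1, H, W) bool
    channel_names: tuple[str, ...]

    def __post_init__(self):
        m = n_event_channels(self.view)
        if self.channels.shape[0] != m + 1:
            raise ValueError(
                f"{self.view} mask needs {m + 1} channels, got {self.channels.shape[0]}"
            )

    @property
    def envelope(self) -> np.ndarray:
        return self.channels[0]

    def event_channel(self, name: str) -> np.ndarray:
        return self.channels[1 + EVENT_VOCAB[self.view].index(name)]


# --------------------------------------------------------------------------
# ground-truth encoding
# --------------------------------------------------------------------------


def encode_truth_mask(
    truth: dict,
    view: str,
    calibration=None,
    band_halfwidth: int = EVENT_BAND_HALFWIDTH,
    band_halfheight: int = EVENT_BAND_HALFHEIGHT,
    shape: tuple[int, int] = DOPPLER_SHAPE,
) -> DelineationMask:
    """Encode a ground-truth record into the (M+1)-channel training mask.

    Channel 0 reproduces the filled envelope region (from the stored fill
    mask, or rebuilt from the per-column envelope rows and the zero line);
    each event occurrence becomes a column band of width
    ``2*band_halfwidth + 1`` spanning ``2*band_halfheight + 1`` rows around
    the envelope row at the event column.
    """
    H, W = shape
    m = n_event_channels(view)
    channels = np.zeros((m + 1, H, W), dtype=bool)

    if "fill_mask" in truth and truth["fill_mask"] is not None:
        channels[0] = np.asarray(truth["fill_mask"], dtype=bool)
    else:
        rows = np.asarray(truth["envelope_row"], dtype=int)
        cal = calibration
        zrow = int(round(cal.zero_line_row))
        for c in range(min(W, rows.size)):
            r = rows[c]
            if r < zrow:
                channels[0, r:zrow, c] = True
            elif r > zrow:
                channels[0, zrow + 1 : r + 1, c] = True

    names = EVENT_VOCAB[view]
    for ev in truth["events"]:
        if ev["name"] not in names:
            raise ValueError(f"event {ev['name']!r} not in {view} vocabulary")
        col, row = int(ev["col"]), int(ev["row"])
        if not (0 <= col < W and 0 <= row < H):
            raise ValueError(f"event {ev['name']!r} at (row {row}, col {col}) outside raster")
        ch = 1 + names.index(ev["name"])
        c0, c1 = max(col - band_halfwidth, 0), min(col + band_halfwidth + 1, W)
        r0, r1 = max(row - band_halfheight, 0), min(row + band_halfheight + 1, H)
        channels[ch, r0:r1, c0:c1] = True
    return DelineationMask(view=view, channels=channels, channel_names=("envelope",) + names)


# --------------------------------------------------------------------------
# U-Net / W-Net
# --------------------------------------------------------------------------


class _ConvBlock(Module):
    def __init__(self, c_in, c_out, n_convs, rng):
        mods = []
        for i in range(n_convs):
            mods.append(Conv2d(c_in if i == 0 else c_out, c_out, 3, rng))
            mods.append(ReLU())
        self.block = nn.Sequential(*mods)

    def forward(self, x, train=False):
        return self.block.forward(x, train=train)

    def backward(self, grad):
        return self.block.backward(grad)


class UNet(Module):
    """U-shaped encoder–decoder returning full-resolution features.

    ``extra_ch[l]`` extra channels are concatenated to the encoder input at
    level ``l`` (used for the cross-U skip connections of the W-Net).
    Returns ``(features, decoder_feats)`` where ``decoder_feats[l]`` is the
    decoder output at level ``l`` (width ``base * 2**l``).
    """

    def __init__(self, c_in, base=8, depth=3, convs_per_block=1, extra_ch=None, rng=None):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.base = base
        self.extra_ch = list(extra_ch) if extra_ch else [0] * depth
        w = [base * 2**l for l in range(depth)]
        self.widths = w
        self.enc = []
        for l in range(depth - 1):
            cin = (c_in if l == 0 else w[l - 1]) + self.extra_ch[l]
            self.enc.append(_ConvBlock(cin, w[l], convs_per_block, rng))
        self.bott = _ConvBlock(w[depth - 2] + self.extra_ch[depth - 1], w[depth - 1], convs_per_block, rng)
        self.dec = []
        for l in range(depth - 2, -1, -1):
            self.dec.append(_ConvBlock(w[l + 1] + w[l], w[l], convs_per_block, rng))
        self._cache = None

    def forward(self, x, extra=None, train=False):
        depth = self.depth
        pools = []
        enc_feats = []
        cat_in = []  # channels of (main, extra) at each encoder level
        h = x
        for l in range(depth - 1):
            if self.extra_ch[l]:
                cat_in.append((h.shape[3], extra[l].shape[3]))
                h = np.concatenate([h, extra[l]], axis=3)
            else:
                cat_in.append(None)
            h = self.enc[l].forward(h, train=train)
            enc_feats.append(h)
            pool = MaxPool2d()
            h = pool.forward(h, train=train)
            pools.append(pool)
        if self.extra_ch[depth - 1]:
            cat_in.append((h.shape[3], extra[depth - 1].shape[3]))
            h = np.concatenate([h, extra[depth - 1]], axis=3)
        else:
            cat_in.append(None)
        h = self.bott.forward(h, train=train)
        dec_feats = [None] * (depth - 1)
        ups = []
        for i, l in enumerate(range(depth - 2, -1, -1)):
            up = Upsample2d()
            h = up.forward(h, train=train)
            ups.append(up)
            h = np.concatenate([h, enc_feats[l]], axis=3)
            h = self.dec[i].forward(h, train=train)
            dec_feats[l] = h
        if train:
            self._cache = dict(pools=pools, ups=ups, cat_in=cat_in)
        return h, dec_feats

    def backward(self, dout, ddec_extra=None):
        """Backprop; ``ddec_extra[l]`` adds gradient flowing into the level-l
        decoder features from outside (cross-U skips).  Returns
        ``(dx, dextra)``."""
        depth = self.depth
        cache = self._cache
        pools, ups, cat_in = cache["pools"], cache["ups"], cache["cat_in"]
        dextra = [None] * depth
        denc = [None] * (depth - 1)
        g = dout
        for i, l in enumerate(range(0, depth - 1)):  # decoder blocks in reverse
            di = (depth - 2) - l  # index into self.dec for level l
            if ddec_extra and ddec_extra.get(l) is not None:
                g = g + ddec_extra[l]
            g = self.dec[di].backward(g)
            w_up = self.widths[l + 1]
            g_up, g_skip = g[..., :w_up], g[..., w_up:]
            denc[l] = g_skip
            g = ups[di].backward(g_up)
        g = self.bott.backward(g)
        if cat_in[depth - 1] is not None:
            n_main, _ = cat_in[depth - 1]
            g, dextra[depth - 1] = g[..., :n_main], g[..., n_main:]
        for l in range(depth - 2, -1, -1):
            g = pools[l].backward(g)
            g = g + denc[l]
            g = self.enc[l].backward(g)
            if cat_in[l] is not None:
                n_main, _ = cat_in[l]
                g, dextra[l] = g[..., :n_main], g[..., n_main:]
        self._cache = None
        return g, dextra


@dataclass
class WNetSpec:
    view: str
    base_width: int = 8
    depth: int = 3
    convs_per_block: int = 1

    @property
    def out_channels(self) -> int:
        return n_event_channels(self.view) + 1


class WNet(Module):
    """Two stacked U-Nets with cross-U skip connections and an
    (M+1)-channel sigmoid output head."""

    def __init__(self, spec: WNetSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        b, d, cpb = spec.base_width, spec.depth, spec.convs_per_block
        self.u1 = UNet(1, b, d, cpb, rng=rng)
        # cross-U skips: U1 decoder features at levels 1..depth-2 feed the
        # matching U2 encoder levels
        extra = [0] * d
        for l in range(1, d - 1):
            extra[l] = b * 2**l
        self.u2 = UNet(b, b, d, cpb, extra_ch=extra, rng=rng)
        self.head = Conv2d(b, spec.out_channels, 1, rng)
        # start the rare event channels sparse (p ~ 0.02): the overlap loss
        # is ill-conditioned when |P| >> |T| at initialization
        self.head.b.value[1:] = -4.0
        self._cross_levels = [l for l in range(d) if extra[l]]

    def forward(self, x, train: bool = False):
        f1, d1 = self.u1.forward(x, train=train)
        extra = [d1[l] if l in self._cross_levels else None for l in range(self.spec.depth)]
        f2, _ = self.u2.forward(f1, extra=extra, train=train)
        return self.head.forward(f2, train=train)

    def backward(self, dlogits):
        df2 = self.head.backward(dlogits)
        df1, dextra = self.u2.backward(df2)
        ddec = {l: dextra[l] for l in self._cross_levels}
        dx, _ = self.u1.backward(df1, ddec_extra=ddec)
        return dx

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        from .nn.layers import state_dict

        arrays = {f"param_{i}": a for i, a in enumerate(state_dict(self))}
        np.savez_compressed(
            path,
            view=self.spec.view,
            base_width=self.spec.base_width,
            depth=self.spec.depth,
            convs_per_block=self.spec.convs_per_block,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "WNet":
        from .nn.layers import load_state_dict

        z = np.load(path, allow_pickle=False)
        spec = WNetSpec(
            view=str(z["view"]),
            base_width=int(z["base_width"]),
            depth=int(z["depth"]),
            convs_per_block=int(z["convs_per_block"]),
        )
        model = cls(spec)
        n = len([k for k in z.files if k.startswith("param_")])
        load_state_dict(model, [z[f"param_{i}"] for i in range(n)])
        return model


def build_wnet(view: str, width_config: str = "reduced", seed: int = 0) -> WNet:
    """Per-view W-Net; ``width_config`` is ``reduced`` (base 8, depth 3,
    single conv per block — the desk-scale default) or ``full`` (base 32,
    depth 5, double convs)."""
    if view not in ALL_VIEWS:
        raise ValueError(f"unknown view {view!r}")
    if width_config == "reduced":
        spec = WNetSpec(view=view, base_width=8, depth=3, convs_per_block=1)
    elif width_config == "full":
        spec = WNetSpec(view=view, base_width=32, depth=5, convs_per_block=2)
    else:
        raise ValueError(f"width_config must be 'reduced' or 'full', got {width_config!r}")
    return WNet(spec, seed=seed)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


@dataclass
class DelineationHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    n_train_pairs: int = 0


GRID = 8  # pooling stride product of the depth-3 W-Net


def _random_crop(img, mask, size, rng, p_event: float = 0.5):
    """Random square crop aligned to the pooling grid.

    Alignment keeps the pooling phase identical between crop training and
    full-raster inference.  With probability ``p_event`` the crop is placed
    around a random event-band pixel (uniformly positioned within the crop)
    so the rare event channels see positive targets often enough for the
    overlap loss to learn them.
    """
    H, W = img.shape
    rmax, cmax = max(H - size, 0), max(W - size, 0)
    r0 = c0 = 0
    if rng.random() < p_event and mask.shape[0] > 1:
        rows, cols = np.where(mask[1:].any(axis=0))
        if rows.size:
            i = int(rng.integers(rows.size))
            m = 6
            jr = int(rng.integers(-size // 2 + m, size // 2 - m + 1))
            jc = int(rng.integers(-size // 2 + m, size // 2 - m + 1))
            r0 = int(np.clip(rows[i] - size // 2 + jr, 0, rmax))
            c0 = int(np.clip(cols[i] - size // 2 + jc, 0, cmax))
    else:
        r0 = int(rng.integers(0, rmax + 1)) if rmax else 0
        c0 = int(rng.integers(0, cmax + 1)) if cmax else 0
    r0 = (r0 // GRID) * GRID
    c0 = (c0 // GRID) * GRID
    return img[r0 : r0 + size, c0 : c0 + size], mask[:, r0 : r0 + size, c0 : c0 + size]


def train_delineator(
    train_set,
    view: str,
    train_config=None,
    val_set=None,
    augment_fn=None,
):
    """Train a reduced W-Net on (spectrogram, mask-channels) pairs.

    ``train_set`` is a list of ``(image (H, W) float, channels (M+1, H, W))``
    pairs.  Each pair is duplicated with a vertically flipped copy, then at
    every epoch a random square crop of each (possibly augmented) image is
    drawn; optimization is Adam on the combined soft Dice + soft F1 loss
    with a reduce-on-plateau schedule monitoring validation loss.
    Returns ``(model, history)``.
    """
    from .training import TrainConfig

    cfg = train_config or TrainConfig(epochs=20)
    if len(train_set) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)

    def flip(img, ch):
        return img[::-1].copy(), ch[:, ::-1].copy()

    pairs = []
    for img, ch in train_set:
        img = np.asarray(img, dtype=np.float32)
        ch = np.asarray(ch, dtype=np.float32)
        pairs.append((img, ch))
        pairs.append(flip(img, ch))
    if val_set is None:
        n_val = max(2, len(pairs) // 10)
        val_pairs = pairs[:n_val]
        fit_pairs = pairs[n_val:]
    else:
        val_pairs = [(np.asarray(i, dtype=np.float32), np.asarray(c, dtype=np.float32)) for i, c in val_set]
        fit_pairs = pairs

    model = WNet(WNetSpec(view=view, base_width=cfg.base_width, depth=3), seed=cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.plateau_factor, patience=cfg.patience)
    hist = DelineationHistory(n_train_pairs=len(pairs))
    crop = cfg.crop_size
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(fit_pairs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xs, ys = [], []
            for i in idx:
                img, ch = fit_pairs[i]
                if augment_fn is not None:
                    img, ch = augment_fn(img, ch, rng)
                ci, cm = _random_crop(img, ch, crop, rng)
                xs.append(ci[:, :, None])
                ys.append(np.moveaxis(cm, 0, -1))
            x = np.stack(xs).astype(np.float32)
            y = np.stack(ys).astype(np.float32)
            logits = model.forward(x, train=True)
            loss, dz = dice_f1_loss(logits, y, smooth=cfg.loss_smooth)
            if cfg.bce_weight > 0:
                # auxiliary cross-entropy: keeps gradient flowing into event
                # channels whose sigmoids saturate under the overlap loss
                bl, bdz = bce_loss(logits, y)
                dz = dz + cfg.bce_weight * bdz
                loss = loss + cfg.bce_weight * bl
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        # deterministic central-crop validation
        vlosses = []
        for img, ch in val_pairs:
            H, W = img.shape
            r0, c0 = (H - crop) // 2, (W - crop) // 2
            x = img[None, r0 : r0 + crop, c0 : c0 + crop, None].astype(np.float32)
            y = np.moveaxis(ch[:, r0 : r0 + crop, c0 : c0 + crop], 0, -1)[None].astype(
                np.float32
            )
            loss, _ = dice_f1_loss(model.forward(x), y, smooth=cfg.loss_smooth)
            vlosses.append(loss)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(np.mean(vlosses)))
        hist.lr.append(opt.lr)
        sched.step(hist.val_loss[-1])
    return model, hist


def predict_masks(model: WNet, doppler: np.ndarray, threshold: float = 0.5) -> DelineationMask:
    """Sigmoid probabilities thresholded at 0.5, per channel."""
    x = np.asarray(doppler, dtype=np.float32)[None, :, :, None]
    logits = model.forward(x)
    prob = sigmoid(logits[0])  # (H, W, M+1)
    view = model.spec.view
    return DelineationMask(
        view=view,
        channels=np.moveaxis(prob >= threshold, -1, 0),
        channel_names=("envelope",) + EVENT_VOCAB[view],
    )


def dice_coefficient(pred: np.ndarray, target: np.ndarray) -> float:
    """Hard Dice overlap of two binary masks (1.0 when both empty)."""
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(target, dtype=bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)
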