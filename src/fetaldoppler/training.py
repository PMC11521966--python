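"""Shared training scaffolding: configs, augmentation, patient-level splits.

Augmentations mirror the recipe used for both model families: brightness
and contrast jitter, flips, rotation and scaling, plus two Doppler-specific
operations — elimination of empty rows beyond the signal span and synthetic
aliasing that folds supra-threshold envelope content onto the opposite edge
of the raster.  Geometric operations are applied with identical parameters
to an image and its mask so the two stay congruent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class TrainConfig:
    """Optimization settings shared by the classifier and delineator.

    Defaults follow the training recipe: batch size 16, Adam at 1e-3 with a
    reduce-on-plateau schedule (factor 0.1, patience 20 epochs); 200 epochs
    for classifiers and 100 for delineation at full scale — both reducible
    for desk-scale runs.
    """

    batch_size: int = 16
    epochs: int = 100
    lr: float = 1e-3
    plateau_factor: float = 0.1
    patience: int = 20
    seed: int = 0
    # delineation-specific knobs
    base_width: int = 8
    crop_size: int = 128
    loss_smooth: float = 1.0
    #: weight of the auxiliary binary cross-entropy stabilizer added to the
    #: Dice/F1 objective during delineation training (0 disables it)
    bce_weight: float = 0.3

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.patience) <= 0 or self.lr <= 0:
            raise ValueError("batch_size, epochs, patience and lr must be positive")
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau_factor must lie in (0, 1)")


@dataclass
class AugmentationConfig:
    """Per-epoch augmentation magnitudes; probabilities in [0, 1]."""

    brightness_range: tuple[float, float] = (-0.2, 0.2)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    p_hflip: float = 0.0  # time reversal — classifier training only
    p_vflip: float = 0.5
    rotation_deg: float = 10.0
    p_rotate: float = 0.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    p_scale: float = 0.0
    p_row_elimination: float = 0.0
    p_aliasing: float = 0.0
    aliasing_fraction: float = 0.25  # top fraction of the signal span folded
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_hflip, self.p_vflip, self.p_rotate, self.p_scale,
                  self.p_row_elimination, self.p_aliasing):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


def _geometric(img, angle=None, scale=None):
    out = img
    if angle:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    if scale and scale != 1.0:
        zoomed = ndimage.zoom(out, scale, order=1, mode="nearest")
        out = _center_fit(zoomed, img.shape)
    return out


def _center_fit(img, shape):
    """Center-crop or zero-pad ``img`` to ``shape``."""
    out = np.zeros(shape, dtype=img.dtype)
    h, w = img.shape
    H, W = shape
    ch, cw = min(h, H), min(w, W)
    r0s, c0s = (h - ch) // 2, (w - cw) // 2
    r0d, c0d = (H - ch) // 2, (W - cw) // 2
    out[r0d : r0d + ch, c0d : c0d + cw] = img[r0s : r0s + ch, c0s : c0s + cw]
    return out


def augment_pair(image: np.ndarray, mask_or_label, config: AugmentationConfig, rng):
    """Apply one random augmentation draw to an image and its mask/label.

    ``mask_or_label`` is either an integer class label (classification) or
    an (M+1, H, W) mask transformed congruently with the image.  If an
    augmentation would empty the envelope mask the sample is returned
    unaugmented with a warning.
    """
    img = np.asarray(image, dtype=np.float32)
    has_mask = isinstance(mask_or_label, np.ndarray)
    mask = mask_or_label.astype(np.float32) if has_mask else None

    out = img.copy()
    # photometric — image only
    b = rng.uniform(*config.brightness_range)
    c = rng.uniform(*config.contrast_range)
    out = np.clip((out - 0.5) * c + 0.5 + b, 0.0, 1.0)

    flip_h = rng.random() < config.p_hflip
    flip_v = rng.random() < config.p_vflip
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg) if rng.random() < config.p_rotate else None
    scale = rng.uniform(*config.scale_range) if rng.random() < config.p_scale else None
    do_rows = rng.random() < config.p_row_elimination
    do_alias = rng.random() < config.p_aliasing

    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1]
    out = _geometric(out, angle, scale)

    if not has_mask:
        return np.ascontiguousarray(out), mask_or_label

    mch = mask.copy()
    if flip_h:
        mch = mch[:, :, ::-1]
    if flip_v:
        mch = mch[:, ::-1]
    if angle or scale:
        mch = np.stack([
            (_geometric(ch, angle, scale) > 0.5).astype(np.float32) for ch in mch
        ])

    if do_rows:
        out, mch = _eliminate_rows(out, mch)
    if do_alias:
        out, mch = _synthetic_aliasing(out, mch, config.aliasing_fraction)

    if mch[0].sum() == 0:
        warnings.warn("augmentation emptied the envelope mask; sample left unaugmented")
        return img, mask_or_label
    return np.ascontiguousarray(out), np.ascontiguousarray(mch)


def _eliminate_rows(img, mask):
    """Drop empty rows beyond the signal span, then pad back to shape."""
    env = mask[0]
    rows = np.where(env.any(axis=1))[0]
    if rows.size == 0:
        return img, mask
    margin = 4
    r0 = max(int(rows.min()) - margin, 0)
    r1 = min(int(rows.max()) + margin + 1, img.shape[0])
    H = img.shape[0]
    img2 = np.zeros_like(img)
    mask2 = np.zeros_like(mask)
    h = r1 - r0
    img2[:h] = img[r0:r1]
    mask2[:, :h] = mask[:, r0:r1]
    return img2, mask2


def _synthetic_aliasing(img, mask, fraction):
    """Fold the top ``fraction`` of the occupied row span to the opposite
    edge of the raster, in both the image and the envelope mask."""
    env = mask[0]
    rows = np.where(env.any(axis=1))[0]
    if rows.size == 0:
        return img, mask
    H = img.shape[0]
    r_lo, r_hi = int(rows.min()), int(rows.max())
    cut = int(r_lo + fraction * (r_hi - r_lo))
    if cut <= r_lo:
        return img, mask
    img2 = img.copy()
    mask2 = mask.copy()
    band_img = img[r_lo:cut].copy()
    band_env = env[r_lo:cut].copy()
    img2[r_lo:cut] = 0.0
    mask2[0, r_lo:cut] = 0.0
    h = cut - r_lo
    img2[H - h :] = np.maximum(img2[H - h :], band_img)
    mask2[0, H - h :] = np.maximum(mask2[0, H - h :], band_env)
    return img2, mask2


# --------------------------------------------------------------------------
# dataset splitting
# --------------------------------------------------------------------------


def stratified_patient_split(index, train_frac: float = 0.75, seed: int = 0):
    """Split image ids into train/test, stratified by class, with every
    patient entirely on one side.

    ``index`` is a DataFrame-like with columns ``study_id`` (or ``path``),
    ``label`` and ``patient_id``.  Within each class, patients are shuffled
    and assigned to the training side until it holds ``train_frac`` of the
    class's images.  Returns ``(train_ids, test_ids)``.
    """
    import pandas as pd

    df = pd.DataFrame(index)
    id_col = "study_id" if "study_id" in df.columns else "path"
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    # stratify by each patient's (single) class; patients spanning classes
    # are assigned by their majority class
    pat_label = df.groupby("patient_id")["label"].agg(lambda s: s.mode().iloc[0])
    for label in sorted(df["label"].unique()):
        pats = sorted(pat_label[pat_label == label].index)
        counts = df[df["patient_id"].isin(pats)].groupby("patient_id")[id_col].count()
        n_images = int(counts.sum())
        if len(pats) == 1 or counts.max() > train_frac * n_images:
            warnings.warn(
                f"class {label!r}: one patient dominates; best-effort patient split"
            )
        order = list(rng.permutation(pats))
        target = train_frac * n_images
        taken = 0
        train_pats = []
        for p in order:
            if taken < target:
                train_pats.append(p)
                taken += int(counts[p])
        sub = df[df["patient_id"].isin(pats)]
        in_train = sub["patient_id"].isin(train_pats)
        train_ids.extend(sub.loc[in_train, id_col].tolist())
        test_ids.extend(sub.loc[~in_train, id_col].tolist())
    return train_ids, test_ids
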