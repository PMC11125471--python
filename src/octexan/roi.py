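"""ROI segmentation between the ILM and RPE with a nested U-Net.

The retina's EX-AN lesions occur only in the band between the internal
limiting membrane and the retinal pigment epithelium, so the pipeline
first segments that band. A U-Net++ is trained on random patches with
geometric augmentation under a BCE + Dice loss; full-image inference
tiles the scan with half-patch stride and averages overlapping
probability maps; the binary ROI is the thresholded map's largest
connected component, from which per-column ILM/RPE boundary curves are
read off as the first/last mask row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from octexan import nn
from octexan.preprocess import NormalizedImage

EPS = 1e-7


class RoiConfigError(ValueError):
    pass


class NoRoiError(RuntimeError):
    """Raised when a predicted/provided ROI mask is empty."""


@dataclass(frozen=True)
class AugmentConfig:
    rotation_deg: float = 25.0
    zoom_range: tuple[float, float] = (0.5, 1.2)
    distortion_grid: int = 3
    distortion_magnitude_range: tuple[float, float] = (1.0, 8.0)
    hflip: bool = True
    p_apply: float = 0.5  # independent activation probability per transform


@dataclass(frozen=True)
class UnetPPConfig:
    depth: int = 4
    base_filters: int = 32
    batch_norm: bool = True
    output_threshold: float = 0.5
    patch_size: int = 224
    patches_per_image: int = 300
    epochs: int = 50
    batch_size: int = 4
    learning_rate: float = 1e-4
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    keep_largest_component: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if self.patch_size % 2 ** (self.depth - 1) != 0:
            raise RoiConfigError(
                f"patch_size {self.patch_size} not divisible by 2^(depth-1) = {2 ** (self.depth - 1)}"
            )
        if not 0.0 < self.output_threshold < 1.0:
            raise RoiConfigError("output_threshold must lie in (0, 1)")


def scaled_down_config(**overrides) -> UnetPPConfig:
    """Desk-scale training recipe for CPU-only runs on synthetic scenes."""
    defaults = dict(base_filters=8, patch_size=64, patches_per_image=6,
                    epochs=10, learning_rate=1e-3)
    defaults.update(overrides)
    return UnetPPConfig(**defaults)


@dataclass
class LayerBoundaries:
    """Per-column ILM/RPE rows plus the mask between them.

    ``ilm``/``rpe`` are float arrays with NaN at columns where the ROI
    mask is empty.
    """

    ilm: np.ndarray
    rpe: np.ndarray
    roi_mask: np.ndarray

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.ilm)


def build_model(config: UnetPPConfig) -> nn.UNetPP:
    config.validate()
    return nn.UNetPP(depth=config.depth, base_filters=config.base_filters,
                     batch_norm=config.batch_norm, rng_seed=config.rng_seed)


def bce_dice_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Sum of pixel-mean binary cross-entropy and Dice loss.

    ``L_BCE = mean(−[y log p + (1−y) log(1−p)])`` over pixels and
    ``L_D = 1 − 2Σ(y·p)/(Σy + Σp)`` over the whole array. Probabilities
    are clamped to ``[EPS, 1−EPS]`` so exact 0/1 never produces NaN.
    """
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same shape")
    bce = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
    denom = float(y.sum() + p.sum())
    dice = 1.0 - 2.0 * float((y * p).sum()) / denom if denom > 0 else 0.0
    return bce + dice


def extract_patches(image: np.ndarray, mask: np.ndarray, config: UnetPPConfig,
                    rng: np.random.Generator | None = None):
    """Random aligned (patch, mask) crops of ``patch_size``; seeded."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    ps = config.patch_size
    h, w = image.shape
    if h < ps or w < ps:
        raise RoiConfigError(f"image of shape {image.shape} smaller than patch size {ps}")
    out = []
    for _ in range(config.patches_per_image):
        y = int(rng.integers(0, h - ps + 1))
        x = int(rng.integers(0, w - ps + 1))
        out.append((image[y : y + ps, x : x + ps].copy(), mask[y : y + ps, x : x + ps].copy()))
    return out


def _grid_distortion_field(shape, grid: int, magnitude: float, rng: np.random.Generator):
    ctrl = rng.uniform(-magnitude, magnitude, size=(2, grid, grid))
    zoom_f = ((shape[0] - 1) / (grid - 1), (shape[1] - 1) / (grid - 1))
    dy = ndimage.zoom(ctrl[0], zoom_f, order=1)
    dx = ndimage.zoom(ctrl[1], zoom_f, order=1)
    return dy[: shape[0], : shape[1]], dx[: shape[0], : shape[1]]


def augment(patch: np.ndarray, mask: np.ndarray, config: UnetPPConfig,
            rng: np.random.Generator):
    """Randomly rotate, flip, zoom and grid-distort a patch/mask pair.

    Each transform activates independently with probability
    ``augmentation.p_apply``; the identical geometric transform is
    applied to the patch and its mask, and the mask is re-binarized at
    0.5 after interpolation.
    """
    a = config.augmentation
    img = patch.astype(float)
    msk = mask.astype(float)

    if a.hflip and rng.uniform() < a.p_apply:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()

    angle = 0.0
    if a.rotation_deg > 0 and rng.uniform() < a.p_apply:
        angle = float(rng.uniform(-a.rotation_deg, a.rotation_deg))
    zoom = 1.0
    if rng.uniform() < a.p_apply:
        zoom = float(rng.uniform(*a.zoom_range))
    if angle != 0.0 or zoom != 1.0:
        c, s = np.cos(np.deg2rad(angle)), np.sin(np.deg2rad(angle))
        mat = np.array([[c, -s], [s, c]]) / zoom
        center = (np.array(img.shape) - 1) / 2.0
        offset = center - mat @ center
        img = ndimage.affine_transform(img, mat, offset=offset, order=1, mode="nearest")
        msk = ndimage.affine_transform(msk, mat, offset=offset, order=1, mode="nearest")

    if a.distortion_magnitude_range[1] > 0 and rng.uniform() < a.p_apply:
        mag = float(rng.uniform(*a.distortion_magnitude_range))
        dy, dx = _grid_distortion_field(img.shape, a.distortion_grid, mag, rng)
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
        coords = np.stack([yy + dy, xx + dx])
        img = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        msk = ndimage.map_coordinates(msk, coords, order=1, mode="nearest")

    return img, (msk >= 0.5).astype(float)


def _loss_and_grad(model: nn.UNetPP, xb: np.ndarray, yb: np.ndarray):
    """One fused forward/backward pass; returns the scalar batch loss."""
    logits = model.forward(xb, train=True)
    p = nn.sigmoid(logits)
    n, _, hh, ww = p.shape
    npix = p.size
    pc = np.clip(p.astype(float), EPS, 1 - EPS)
    bce = float(np.mean(-(yb * np.log(pc) + (1 - yb) * np.log(1 - pc))))
    dlogit = (p - yb) / npix  # d(BCE)/d(logit) through the sigmoid
    dice_terms = []
    ddice_dp = np.zeros_like(p)
    for i in range(n):
        yi, pi = yb[i], p[i]
        sy, sp, syp = float(yi.sum()), float(pi.sum()), float((yi * pi).sum())
        denom = sy + sp + EPS
        dice_terms.append(1.0 - 2.0 * syp / denom)
        ddice_dp[i] = (-2.0 * yi * denom + 2.0 * syp) / denom**2 / n
    dlogit = dlogit + ddice_dp * p * (1 - p)
    model.zero_grad()
    model.backward(dlogit)
    return bce + float(np.mean(dice_terms))


def train(model: nn.UNetPP, dataset, config: UnetPPConfig, val_fraction: float = 0.1):
    """Train on (image, roi_mask) pairs; returns per-epoch loss history.

    ``dataset`` is a sequence of ``(image, mask)`` arrays. The split into
    train/validation is at image level (90/10 by default) to avoid patch
    leakage. Patches are drawn once per image and re-augmented each
    epoch. Fully deterministic given ``config.rng_seed``.
    """
    config.validate()
    if len(dataset) < 2:
        raise RoiConfigError("training requires at least 2 images")
    rng = np.random.default_rng(config.rng_seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(val_fraction * len(dataset))))
    val_ids, train_ids = order[:n_val], order[n_val:]

    train_patches = []
    for idx in train_ids:
        img, msk = dataset[idx]
        train_patches += extract_patches(np.asarray(img, float), np.asarray(msk, float), config, rng)
    val_patches = []
    for idx in val_ids:
        img, msk = dataset[idx]
        val_patches += extract_patches(np.asarray(img, float), np.asarray(msk, float), config, rng)

    opt = nn.RMSprop(model.params(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    for _epoch in range(config.epochs):
        perm = rng.permutation(len(train_patches))
        losses = []
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start : start + config.batch_size]
            xs, ys = [], []
            for b in batch:
                pi, mi = augment(*train_patches[b], config, rng)
                xs.append(pi)
                ys.append(mi)
            xb = np.stack(xs)[:, None].astype(nn.DTYPE)
            yb = np.stack(ys)[:, None].astype(nn.DTYPE)
            losses.append(_loss_and_grad(model, xb, yb))
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
        vlosses = []
        for start in range(0, len(val_patches), config.batch_size):
            chunk = val_patches[start : start + config.batch_size]
            xb = np.stack([c[0] for c in chunk])[:, None].astype(nn.DTYPE)
            yb = np.stack([c[1] for c in chunk])[:, None]
            p = nn.sigmoid(model.forward(xb, train=False))
            vlosses.append(bce_dice_loss(yb, p))
        history["val_loss"].append(float(np.mean(vlosses)) if vlosses else float("nan"))
    return model, history


def predict_roi(model: nn.UNetPP, image: NormalizedImage | np.ndarray,
                config: UnetPPConfig):
    """Full-image probability map + binary ROI mask.

    The map is assembled by sliding-window tiling with stride
    ``patch_size/2`` and per-pixel averaging of overlapping tiles; the
    mask is ``map > output_threshold`` reduced to its largest connected
    component (the retina is a single band).
    """
    pixels = image.pixels if isinstance(image, NormalizedImage) else np.asarray(image, float)
    ps = config.patch_size
    h, w = pixels.shape
    if h < ps or w < ps:
        raise RoiConfigError(f"image of shape {pixels.shape} smaller than patch size {ps}")
    stride = ps // 2
    ys = sorted(set(list(range(0, h - ps + 1, stride)) + [h - ps]))
    xs = sorted(set(list(range(0, w - ps + 1, stride)) + [w - ps]))
    acc = np.zeros((h, w), dtype=float)
    cnt = np.zeros((h, w), dtype=float)
    tiles = [(y, x) for y in ys for x in xs]
    batch = 8
    for start in range(0, len(tiles), batch):
        chunk = tiles[start : start + batch]
        xb = np.stack([pixels[y : y + ps, x : x + ps] for y, x in chunk])[:, None]
        pb = nn.sigmoid(model.forward(xb.astype(nn.DTYPE), train=False))[:, 0]
        for (y, x), p in zip(chunk, pb):
            acc[y : y + ps, x : x + ps] += p
            cnt[y : y + ps, x : x + ps] += 1.0
    prob = acc / cnt
    mask = prob > config.output_threshold
    if config.keep_largest_component and mask.any():
        lab = cc_label(mask, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == sizes.argmax()
    return prob, mask


def boundaries_from_mask(roi_mask: np.ndarray) -> LayerBoundaries:
    """Per-column first/last mask row as the ILM/RPE boundary curves."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise NoRoiError("no ROI detected: empty mask")
    h, w = roi_mask.shape
    rows = np.arange(h)[:, None]
    has = roi_mask.any(axis=0)
    ilm = np.full(w, np.nan)
    rpe = np.full(w, np.nan)
    ilm[has] = np.where(roi_mask, rows, h).min(axis=0)[has]
    rpe[has] = np.where(roi_mask, rows, -1).max(axis=0)[has]
    return LayerBoundaries(ilm=ilm, rpe=rpe, roi_mask=roi_mask)


def save_model(model: nn.UNetPP, config: UnetPPConfig, path: str | Path) -> None:
    """Serialize weights + config to a single ``.npz`` file."""
    state = model.state_dict()
    cfg = asdict(config)
    np.savez_compressed(Path(path), __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **state)


def load_model(path: str | Path):
    data = np.load(Path(path))
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    cfg_dict["augmentation"] = AugmentConfig(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in cfg_dict["augmentation"].items()
    })
    config = UnetPPConfig(**cfg_dict)
    model = build_model(config)
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model, config
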