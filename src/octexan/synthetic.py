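"""Parametric OCT-like B-scan simulator with full ground truth.

A synthetic scene mimics the anatomy the segmentation pipeline relies on:
a wing-shaped ILM curve with a foveal dip (or an inverted "mountain" apex
in diseased scenes), stacked gray inner layers, a thin bright RPE band,
small hyperreflective EX-AN blobs strictly inside the ILM-RPE band that
cast thin dark shadow columns, bright distractor blobs sitting on the
ILM/RPE bands or over cysts (the classifier's documented error modes),
dark cystic regions, and multiplicative speckle noise.

Coordinates are 0-based ``(row=y, col=x)`` with y growing downward; all
intensities are normalized to [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EXAN = "EXAN"
DISTRACTOR = "DISTRACTOR"


class SceneConfigError(ValueError):
    """Raised when a scene configuration describes impossible geometry."""


@dataclass(frozen=True)
class IlmParams:
    """Shape of the ILM boundary curve.

    The curve is ``baseline − A·((x−cx)/(W/2))² + s·depth·exp(−(x−fx)²/2σ²)``:
    a baseline row minus two raised flanks (the "wing") plus a Gaussian
    foveal dip at ``fovea_x``. ``sign=+1`` dips toward the RPE (normal
    fovea); ``sign=−1`` produces the upward mountain-like apex seen when
    cysts or hemorrhage displace the fovea.
    """

    baseline_row: float = 60.0
    wing_amplitude: float = 10.0
    fovea_x: float | None = None  # None -> image center
    fovea_depth: float = 14.0
    fovea_sign: int = 1
    fovea_sigma: float = 14.0


@dataclass(frozen=True)
class SceneConfig:
    image_height: int = 192
    image_width: int = 256
    ilm: IlmParams = field(default_factory=IlmParams)
    rpe_row: int = 150
    rpe_thickness: int = 3
    n_exan_blobs: int = 5
    blob_radius_range: tuple[float, float] = (1.5, 3.5)
    blob_intensity_range: tuple[float, float] = (0.75, 0.95)
    shadow_attenuation: float = 0.3
    n_distractor_blobs: int = 3
    n_cysts: int = 1
    speckle_sigma: float = 0.03
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise SceneConfigError("image must be at least 32x32 pixels")
        for lo, hi, name in [
            (*self.blob_intensity_range, "blob_intensity_range"),
            (self.shadow_attenuation, self.shadow_attenuation, "shadow_attenuation"),
            (self.speckle_sigma, self.speckle_sigma, "speckle_sigma"),
        ]:
            if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
                raise SceneConfigError(f"{name} must lie in [0, 1]")
        curve = ilm_curve(self)
        if not np.all(curve < self.rpe_row):
            raise SceneConfigError("ILM curve must lie strictly above rpe_row at every column")
        if curve.min() < 1:
            raise SceneConfigError("ILM curve leaves the image at the top")
        if self.rpe_row + self.rpe_thickness + 1 >= self.image_height:
            raise SceneConfigError("RPE band leaves the image at the bottom")


@dataclass(frozen=True)
class SceneBlob:
    """A ground-truth blob: labeled pixel set with derived geometry."""

    label: str
    pixels: np.ndarray  # (n, 2) array of (y, x)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        y, x = self.pixels[:, 0], self.pixels[:, 1]
        return int(y.min()), int(x.min()), int(y.max()), int(x.max())

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean())


@dataclass
class SyntheticScene:
    image: np.ndarray          # (H, W) float in [0, 1]
    ilm: np.ndarray            # per-column integer ILM row
    rpe: np.ndarray            # per-column integer RPE row (top of the band)
    roi_mask: np.ndarray       # bool, ilm(x) <= y <= rpe(x)
    fovea_xy: tuple[float, float]
    blobs: list[SceneBlob]
    cyst_regions: list[np.ndarray]
    config: SceneConfig

    def exan_mask(self) -> np.ndarray:
        """Binary ground-truth mask of EX-AN pixels."""
        m = np.zeros(self.image.shape, dtype=bool)
        for b in self.blobs:
            if b.label == EXAN:
                m[b.pixels[:, 0], b.pixels[:, 1]] = True
        return m


def ilm_curve(config: SceneConfig) -> np.ndarray:
    """Real-valued ILM row per column for the configured wing geometry."""
    p = config.ilm
    x = np.arange(config.image_width, dtype=float)
    cx = (config.image_width - 1) / 2.0
    fx = cx if p.fovea_x is None else float(p.fovea_x)
    flank = p.wing_amplitude * ((x - cx) / (config.image_width / 2.0)) ** 2
    dip = p.fovea_sign * p.fovea_depth * np.exp(-((x - fx) ** 2) / (2.0 * p.fovea_sigma**2))
    return p.baseline_row - flank + dip


def _disk_pixels(cy: float, cx: float, radius: float, shape: tuple[int, int]) -> np.ndarray:
    y0, y1 = int(np.floor(cy - radius)), int(np.ceil(cy + radius))
    x0, x1 = int(np.floor(cx - radius)), int(np.ceil(cx + radius))
    ys, xs = np.mgrid[max(y0, 0) : min(y1, shape[0] - 1) + 1, max(x0, 0) : min(x1, shape[1] - 1) + 1]
    inside = (ys - cy) ** 2 + (xs - cx) ** 2 <= radius**2
    return np.column_stack([ys[inside], xs[inside]])


def _bbox_overlaps(a: np.ndarray, b: np.ndarray, pad: int = 2) -> bool:
    ay0, ax0 = a.min(axis=0); ay1, ax1 = a.max(axis=0)
    by0, bx0 = b.min(axis=0); by1, bx1 = b.max(axis=0)
    return not (ay1 + pad < by0 or by1 + pad < ay0 or ax1 + pad < bx0 or bx1 + pad < ax0)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one scene deterministically from ``config.rng_seed``.

    Raises :class:`SceneConfigError` for impossible geometry (ILM at or
    below the RPE anywhere, out-of-range intensities).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    H, W = config.image_height, config.image_width

    curve = ilm_curve(config)
    ilm_rows = np.round(curve).astype(int)
    rpe_rows = np.full(W, config.rpe_row, dtype=int)
    rows = np.arange(H)[:, None]
    roi = (rows >= ilm_rows[None, :]) & (rows <= rpe_rows[None, :])

    img = np.full((H, W), 0.08)
    # stacked inner layers between ILM and RPE, shades in 0.2-0.5
    depth_frac = (rows - curve[None, :]) / (config.rpe_row - curve[None, :])
    shades = np.array([0.30, 0.22, 0.38, 0.46])
    band_idx = np.clip((depth_frac * len(shades)).astype(int), 0, len(shades) - 1)
    img = np.where(roi, shades[band_idx], img)
    # bright RPE band just below the ROI (the ROI ends at the band's inner surface)
    img[config.rpe_row + 1 : config.rpe_row + 1 + config.rpe_thickness, :] = 0.9
    # choroid under the RPE band
    choroid = rows > (config.rpe_row + config.rpe_thickness)
    img[np.broadcast_to(choroid, img.shape)] = 0.25

    # cysts: dark elliptical regions inside the band
    cysts: list[np.ndarray] = []
    for _ in range(config.n_cysts):
        for _attempt in range(50):
            cx = rng.uniform(20, W - 20)
            ry = rng.uniform(5, 9)
            rx = rng.uniform(8, 16)
            top = ilm_rows[int(cx)] + 8
            bot = config.rpe_row - 6
            if bot - top < 2 * ry + 2:
                continue
            cy = rng.uniform(top + ry, bot - ry)
            ys, xs = np.mgrid[0:H, 0:W]
            inside = ((ys - cy) / ry) ** 2 + ((xs - cx) / rx) ** 2 <= 1.0
            inside &= roi
            if inside.sum() < 4:
                continue
            img[inside] = 0.06
            cysts.append(np.column_stack(np.nonzero(inside)))
            break

    blobs: list[SceneBlob] = []

    # EX-AN blobs: mid-band, near the fovea, shadowed
    cx_img = (W - 1) / 2.0
    fx = cx_img if config.ilm.fovea_x is None else float(config.ilm.fovea_x)
    placed: list[np.ndarray] = []
    for _ in range(config.n_exan_blobs):
        for _attempt in range(200):
            radius = rng.uniform(*config.blob_radius_range)
            bx = float(np.clip(rng.normal(fx, W / 6.0), radius + 2, W - radius - 3))
            col = int(round(bx))
            y_lo = ilm_rows[col] + 5 + radius
            y_hi = config.rpe_row - 5 - radius
            if y_hi <= y_lo:
                continue
            by = rng.uniform(y_lo, y_hi)
            pix = _disk_pixels(by, bx, radius, (H, W))
            if len(pix) == 0 or any(_bbox_overlaps(pix, q) for q in placed):
                continue
            if not roi[pix[:, 0], pix[:, 1]].all():
                continue
            intensity = rng.uniform(*config.blob_intensity_range)
            img[pix[:, 0], pix[:, 1]] = intensity
            # shadow: attenuate everything below the blob footprint
            y_max = pix[:, 0].max()
            for x in np.unique(pix[:, 1]):
                img[y_max + 1 :, x] *= config.shadow_attenuation
            placed.append(pix)
            blobs.append(SceneBlob(EXAN, pix))
            break

    # distractor blobs: on/adjacent to the ILM/RPE bands or over cysts, no shadow
    kinds = ["ilm", "rpe", "cyst"]
    for k in range(config.n_distractor_blobs):
        kind = kinds[k % len(kinds)]
        if kind == "cyst" and not cysts:
            kind = "rpe"
        for _attempt in range(200):
            radius = rng.uniform(*config.blob_radius_range)
            bx = rng.uniform(radius + 2, W - radius - 3)
            col = int(round(bx))
            if kind == "ilm":
                by = float(ilm_rows[col])
            elif kind == "rpe":
                by = float(config.rpe_row + 1)
            else:
                cyst = cysts[k % len(cysts)]
                ctop = cyst[:, 0].min()
                ccx = cyst[:, 1].mean()
                bx = float(np.clip(ccx + rng.uniform(-4, 4), radius + 2, W - radius - 3))
                by = float(max(ctop - radius - 1, ilm_rows[int(round(bx))] + 1))
            pix = _disk_pixels(by, bx, radius, (H, W))
            if len(pix) == 0 or any(_bbox_overlaps(pix, q) for q in placed):
                continue
            intensity = rng.uniform(*config.blob_intensity_range)
            img[pix[:, 0], pix[:, 1]] = intensity
            placed.append(pix)
            blobs.append(SceneBlob(DISTRACTOR, pix))
            break

    if config.speckle_sigma > 0:
        img = img * (1.0 + config.speckle_sigma * rng.standard_normal((H, W)))
    img = np.clip(img, 0.0, 1.0)

    fovea_xy = (fx, float(curve[int(round(fx))]))
    return SyntheticScene(
        image=img, ilm=ilm_rows, rpe=rpe_rows, roi_mask=roi,
        fovea_xy=fovea_xy, blobs=blobs, cyst_regions=cysts, config=config,
    )


def default_config_sampler(index: int, rng: np.random.Generator, **overrides) -> SceneConfig:
    """Draw a per-scene configuration with varied wing geometry.

    Varies flank amplitude, fovea position/depth/width and dip sign so a
    dataset exercises both the normal dip and the abnormal mountain apex.
    """
    width = int(overrides.pop("image_width", 256))
    sign = 1 if rng.uniform() < 0.8 else -1
    ilm = IlmParams(
        baseline_row=float(rng.uniform(52, 68)),
        wing_amplitude=float(rng.uniform(5, 15)),
        fovea_x=float(rng.uniform(0.4, 0.6) * width),
        fovea_depth=float(rng.uniform(10, 20)),
        fovea_sign=sign,
        fovea_sigma=float(rng.uniform(10, 18)),
    )
    kwargs = dict(
        image_width=width,
        ilm=ilm,
        n_exan_blobs=int(rng.integers(3, 8)),
        n_distractor_blobs=int(rng.integers(2, 5)),
        n_cysts=int(rng.integers(0, 2)),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


def generate_dataset(n_scenes: int, config_sampler, out_dir: str | Path, master_seed: int = 0) -> pd.DataFrame:
    """Write ``n_scenes`` scenes (image, ROI mask, annotations) to disk.

    ``config_sampler(index, rng)`` must return a :class:`SceneConfig`.
    Returns the manifest (also written as ``manifest.csv``) listing file
    paths and per-scene seeds.
    """
    from octexan import annotations as ann

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(master_seed)
    records = []
    for i in range(n_scenes):
        cfg = config_sampler(i, rng)
        scene = generate_scene(cfg)
        stem = f"scene_{i:04d}"
        img_path = out_dir / f"{stem}.png"
        mask_path = out_dir / f"{stem}_roi.png"
        ann_path = out_dir / f"{stem}.json"
        ann.write_image(scene.image, img_path)
        ann.write_mask(scene.roi_mask, mask_path)
        ann.write_annotations(scene_to_annotations(stem, scene), ann_path)
        records.append({
            "scene_id": stem, "image": img_path.name, "roi_mask": mask_path.name,
            "annotations": ann_path.name, "rng_seed": cfg.rng_seed,
        })
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def scene_to_annotations(scene_id: str, scene: SyntheticScene) -> dict:
    """Annotation dict (JSON-serializable) for one scene."""
    from octexan import annotations as ann

    return {
        "scene_id": scene_id,
        "image_shape": list(scene.image.shape),
        "fovea_xy": [float(scene.fovea_xy[0]), float(scene.fovea_xy[1])],
        "blobs": [
            {"label": b.label, "rle": ann.rle_encode(b.pixels, scene.image.shape)}
            for b in scene.blobs
        ],
    }
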