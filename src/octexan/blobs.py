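"""Hyperreflective-foci candidate generation.

Candidates are the bright pixels inside the ROI: a pixel survives iff it
lies in the ROI mask and its normalized intensity is at least ``tau``
(default 0.7, the histogram-tail value that best separates EX-AN from
other hyperreflective tissue). Surviving pixels are grouped into
connected components; components smaller than ``min_blob_area`` are
dropped as speckle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label, regionprops

from octexan.preprocess import NormalizedImage


@dataclass(frozen=True)
class ThresholdConfig:
    tau: float = 0.7
    connectivity: int = 8          # 4 or 8
    min_blob_area: int = 2

    def validate(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class Blob:
    """A connected component of candidate pixels."""

    pixel_set: np.ndarray               # (n, 2) array of (y, x)
    bbox: tuple[int, int, int, int]     # y_min, x_min, y_max, x_max (inclusive)
    centroid: tuple[float, float]       # (y_b, x_b)
    area: int

    @property
    def yx(self) -> tuple[float, float]:
        return self.centroid

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixel_set[:, 0], self.pixel_set[:, 1]] = True
        return m


def threshold_roi(img: NormalizedImage | np.ndarray, roi: np.ndarray,
                  cfg: ThresholdConfig = ThresholdConfig()) -> np.ndarray:
    """Binary candidate mask: ROI pixels whose intensity >= tau."""
    cfg.validate()
    pixels = img.pixels if isinstance(img, NormalizedImage) else np.asarray(img, float)
    roi = np.asarray(roi, dtype=bool)
    if pixels.shape != roi.shape:
        raise ValueError(f"image shape {pixels.shape} != roi shape {roi.shape}")
    return roi & (pixels >= cfg.tau)


def label_blobs(candidate_mask: np.ndarray,
                cfg: ThresholdConfig = ThresholdConfig()) -> list[Blob]:
    """Connected components of the candidate mask, sorted by (y_min, x_min)."""
    cfg.validate()
    connectivity = 1 if cfg.connectivity == 4 else 2
    lab = cc_label(np.asarray(candidate_mask, dtype=bool), connectivity=connectivity)
    blobs = []
    for rp in regionprops(lab):
        if rp.area < cfg.min_blob_area:
            continue
        pix = np.asarray(rp.coords)
        y0, x0, y1, x1 = rp.bbox  # bbox end-exclusive in skimage
        blobs.append(Blob(
            pixel_set=pix,
            bbox=(int(y0), int(x0), int(y1 - 1), int(x1 - 1)),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            area=int(rp.area),
        ))
    blobs.sort(key=lambda b: (b.bbox[0], b.bbox[1]))
    return blobs


def extract_candidates(img, roi, cfg: ThresholdConfig = ThresholdConfig()) -> list[Blob]:
    """Threshold + label in one call."""
    return label_blobs(threshold_roi(img, roi, cfg), cfg)


def tune_tau(images_rois_gt, taus=(0.9, 0.8, 0.7, 0.6, 0.5),
             cfg: ThresholdConfig = ThresholdConfig()) -> dict[float, float]:
    """Offline threshold analysis utility.

    For each candidate ``tau``, returns the ratio of EX-AN blobs to all
    blobs whose intensity clears the threshold, over a list of
    ``(image, roi_mask, exan_mask)`` triples. The default pipeline does
    not call this; it documents how a threshold would be chosen on a new
    collection.
    """
    import dataclasses

    ratios = {}
    for tau in taus:
        c = dataclasses.replace(cfg, tau=tau)
        n_blobs = n_exan = 0
        for img, roi, gt in images_rois_gt:
            for b in extract_candidates(img, roi, c):
                n_blobs += 1
                overlap = np.asarray(gt, bool)[b.pixel_set[:, 0], b.pixel_set[:, 1]].sum()
                if overlap / b.area > 0.3:
                    n_exan += 1
        ratios[tau] = n_exan / n_blobs if n_blobs else 0.0
    return ratios
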