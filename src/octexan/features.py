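"""Fovea localization and the nine per-blob features.

The fovea is found on the ILM boundary curve: fit a least-squares line
``L`` to the curve, find where the curve crosses ``L`` (sub-pixel, by
linear interpolation of the residual's sign changes), keep the two
crossings nearest the middle of the curve, and take the fovea as the
curve point between them with maximum absolute perpendicular distance to
``L``. Using the absolute distance makes the same procedure work for the
normal downward foveal pit and the abnormal upward "mountain" apex.

Per candidate blob, nine features are extracted:

==  ============================  =========================================
f1  avg intensity                 mean over the blob's pixels
f2  min intensity                 minimum over the blob's pixels
f3  max intensity                 maximum over the blob's pixels
f4  size                          pixel count
f5  distance to fovea             ``|x_b − x_f|``
f6  distance to ILM               ``|y_b − ILM(x_b)|``
f7  distance to RPE               ``|y_b − RPE(x_b)|``
f8  shadow contrast (left)        ``|mean(m) − mean(l)|``
f9  shadow contrast (right)       ``|mean(m) − mean(r)|``
==  ============================  =========================================

The shadow marker (f8/f9) models the thin dark column an EX-AN casts: a
test rectangle of the blob's width and triple its height sits half a
blob-height below the blob's bounding box, flanked left and right by
rectangles of the same size offset by a 5-px gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from octexan.blobs import Blob
from octexan.preprocess import NormalizedImage
from octexan.roi import LayerBoundaries

FEATURE_NAMES = ["f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8", "f9"]


class BoundaryUndefinedError(ValueError):
    pass


@dataclass(frozen=True)
class ShadowGeometry:
    """Rectangle model beneath a blob: width w, height h, offset u, gap d."""

    w: int
    h: int
    u: int
    d: int = 5


@dataclass(frozen=True)
class FoveaResult:
    fovea_xy: tuple[float, float]       # (x_f, y_f)
    fitted_line: tuple[float, float]    # slope, intercept of L
    intersections: tuple[float, float]  # x positions of p1, p2
    fallback: bool = False              # True when < 2 crossings were found


def detect_fovea(ilm: np.ndarray, smooth_window: int = 15) -> FoveaResult:
    """Locate the fovea on a per-column ILM curve (NaN = undefined).

    ``smooth_window`` applies a centered moving average to the curve
    before fitting: boundary curves read off a binary mask are quantized
    to whole rows, which flattens the foveal apex into a plateau and adds
    unit-step jaggedness; averaging over slightly more than the plateau
    width (about 2*sigma/sqrt(depth) px for a Gaussian pit) restores the
    sub-pixel extremum. Set to 1 to disable.

    Falls back (flagged) to the global maximum-|residual| column when the
    curve crosses its fitted line fewer than two times, e.g. a perfectly
    straight ILM.
    """
    ilm = np.asarray(ilm, dtype=float)
    xs = np.nonzero(~np.isnan(ilm))[0].astype(float)
    if len(xs) < 10:
        raise ValueError("ILM curve must be defined on at least 10 columns")
    ys = ilm[xs.astype(int)]
    if smooth_window > 1:
        k = min(smooth_window, len(ys))
        pad = k // 2
        padded = np.pad(ys, pad, mode="edge")
        ys = np.convolve(padded, np.ones(k) / k, mode="valid")[: len(xs)]
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)

    crossings = []
    for i in range(len(xs) - 1):
        r0, r1 = resid[i], resid[i + 1]
        if r0 == 0.0:
            crossings.append(xs[i])
        elif r0 * r1 < 0:
            crossings.append(xs[i] + r0 / (r0 - r1) * (xs[i + 1] - xs[i]))
    if resid[-1] == 0.0:
        crossings.append(xs[-1])

    mid = (xs[0] + xs[-1]) / 2.0
    if len(crossings) >= 2:
        order = sorted(crossings, key=lambda c: abs(c - mid))
        p1, p2 = sorted(order[:2])
        between = (xs > p1) & (xs < p2)
        if between.any():
            k = np.nonzero(between)[0][np.argmax(np.abs(resid[between]))]
            xf = float(xs[k])
            return FoveaResult((xf, float(ys[k])), (float(slope), float(intercept)),
                               (float(p1), float(p2)))
    # fallback: no usable bracket
    k = int(np.argmax(np.abs(resid)))
    return FoveaResult((float(xs[k]), float(ys[k])), (float(slope), float(intercept)),
                       (float(xs[0]), float(xs[-1])), fallback=True)


def _get_y(curve: np.ndarray, x: float) -> float:
    """Boundary row at (possibly non-integer) column x, linearly interpolated."""
    col = int(round(x))
    if col < 0 or col >= len(curve) or np.isnan(curve[col]):
        raise BoundaryUndefinedError(f"boundary undefined at column {col}")
    x0 = int(np.floor(x))
    x1 = min(x0 + 1, len(curve) - 1)
    if np.isnan(curve[x0]) or np.isnan(curve[x1]):
        return float(curve[col])
    t = x - x0
    return float((1 - t) * curve[x0] + t * curve[x1])


def distance_features(blob: Blob, fovea: FoveaResult, layers: LayerBoundaries):
    """(f5, f6, f7): distances to the fovea, ILM, and RPE."""
    y_b, x_b = blob.centroid
    x_f = fovea.fovea_xy[0]
    try:
        y_ilm = _get_y(layers.ilm, x_b)
        y_rpe = _get_y(layers.rpe, x_b)
    except BoundaryUndefinedError as e:
        raise BoundaryUndefinedError(f"blob at centroid {blob.centroid}: {e}") from e
    return abs(x_b - x_f), abs(y_b - y_ilm), abs(y_b - y_rpe)


def shadow_geometry(blob: Blob) -> ShadowGeometry:
    y0, x0, y1, x1 = blob.bbox
    bw, bh = x1 - x0 + 1, y1 - y0 + 1
    return ShadowGeometry(w=bw, h=3 * bh, u=int(np.ceil(bh / 2)), d=5)


def _rect_mean(img: np.ndarray, y0: int, x0: int, h: int, w: int):
    """Mean over the rectangle clipped to the image; None if nothing survives."""
    H, W = img.shape
    ya, yb = max(y0, 0), min(y0 + h, H)
    xa, xb = max(x0, 0), min(x0 + w, W)
    if ya >= yb or xa >= xb:
        return None
    return float(img[ya:yb, xa:xb].mean())


def shadow_features(blob: Blob, img: NormalizedImage | np.ndarray):
    """(f8, f9): shadow-marker intensity contrasts beneath the blob."""
    pixels = img.pixels if isinstance(img, NormalizedImage) else np.asarray(img, float)
    g = shadow_geometry(blob)
    _y0, x_min, y_max, _x1 = blob.bbox[0], blob.bbox[1], blob.bbox[2], blob.bbox[3]
    top = y_max + g.u
    mean_m = _rect_mean(pixels, top, x_min, g.h, g.w)
    if mean_m is None:
        return 0.0, 0.0
    mean_l = _rect_mean(pixels, top, x_min - (g.w + g.d), g.h, g.w)
    mean_r = _rect_mean(pixels, top, x_min + (g.w + g.d), g.h, g.w)
    f8 = abs(mean_m - mean_l) if mean_l is not None else 0.0
    f9 = abs(mean_m - mean_r) if mean_r is not None else 0.0
    return f8, f9


def extract_features(blobs: list[Blob], img: NormalizedImage | np.ndarray,
                     fovea: FoveaResult, layers: LayerBoundaries) -> pd.DataFrame:
    """One ordered nine-feature row per blob (column ``blob_id`` first)."""
    pixels = img.pixels if isinstance(img, NormalizedImage) else np.asarray(img, float)
    rows = []
    for i, b in enumerate(blobs):
        vals = pixels[b.pixel_set[:, 0], b.pixel_set[:, 1]]
        f5, f6, f7 = distance_features(b, fovea, layers)
        f8, f9 = shadow_features(b, pixels)
        rows.append({
            "blob_id": i,
            "f1": float(vals.mean()), "f2": float(vals.min()), "f3": float(vals.max()),
            "f4": int(b.area), "f5": f5, "f6": f6, "f7": f7, "f8": f8, "f9": f9,
        })
    return pd.DataFrame(rows, columns=["blob_id"] + FEATURE_NAMES)
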