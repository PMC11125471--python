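"""Stable on-disk formats: grayscale PNG images, binary masks, and blob
annotations as JSON with run-length-encoded pixel sets.

RLE runs are ``[start, length]`` pairs over the row-major flattened image
(0-based), so annotations are exact, compact, and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image


class AnnotationError(ValueError):
    pass


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(Path(path))


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG as a 2-D float array on its raw intensity scale.

    Multi-channel inputs with identical channels collapse to channel 0;
    true color is converted by luminance.
    """
    with Image.open(Path(path)) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        ch = arr[..., :3]
        if (ch == ch[..., :1]).all():
            arr = ch[..., 0]
        else:
            arr = ch @ np.array([0.299, 0.587, 0.114])
    return arr.astype(float)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 127


def rle_encode(pixels: np.ndarray, shape: tuple[int, int]) -> list[list[int]]:
    """Run-length encode a set of (y, x) pixels over the row-major flat index."""
    pixels = np.asarray(pixels)
    if len(pixels) == 0:
        return []
    flat = np.sort(pixels[:, 0].astype(np.int64) * shape[1] + pixels[:, 1])
    breaks = np.nonzero(np.diff(flat) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(flat) - 1]])
    return [[int(flat[s]), int(e - s + 1)] for s, e in zip(starts, ends)]


def rle_decode(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    """Decode runs back to an (n, 2) array of (y, x) pixels."""
    idx = np.concatenate([np.arange(s, s + ln) for s, ln in runs]) if runs else np.empty(0, dtype=int)
    return np.column_stack([idx // shape[1], idx % shape[1]]).astype(int)


def write_annotations(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_annotations(path: str | Path) -> dict:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise AnnotationError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}") from e
    for key in ("scene_id", "image_shape", "blobs"):
        if key not in doc:
            raise AnnotationError(f"{path}: missing required key {key!r}")
    return doc
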