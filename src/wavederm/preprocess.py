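"""Image loading, grayscale indexing and the A/A2/A4 resolution pyramid.

Dermoscopy sources arrive as 8-bit RGB; the wavelet analysis consumes a
single indexed-intensity matrix.  The mapping is any fixed linear, strictly
monotone combination of the channels; the default is the ITU-R BT.601 luma
(0.299 R + 0.587 G + 0.114 B), with the plain channel mean available as an
alternative.  Downgraded resolutions are produced by recursive 2x2 block
averaging, and dimensions are fitted to multiples of 2**levels (default 8 for
a depth-3 packet transform) either by appending zero rows/columns at the
bottom/right or by central cropping.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image

RESOLUTIONS = ("A", "A2", "A4")
DOWNSCALE_FACTOR = {"A": 1, "A2": 2, "A4": 4}

_GRAY_MAPS = {
    "luma601": np.array([0.299, 0.587, 0.114]),
    "mean": np.array([1.0, 1.0, 1.0]) / 3.0,
}


def rgb_to_indexed(rgb: np.ndarray, grayscale_map: str = "luma601") -> np.ndarray:
    """Map a 3-channel 8-bit image to indexed grayscale intensities.

    The map is linear and strictly monotone in each channel; gray pixels
    (v, v, v) map to v, so the output range is [0, 255].
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {rgb.shape}")
    try:
        weights = _GRAY_MAPS[grayscale_map]
    except KeyError:
        raise ValueError(f"unknown grayscale_map {grayscale_map!r}") from None
    return rgb @ weights


def downscale_2x2(img: np.ndarray) -> np.ndarray:
    """Average disjoint 2x2 blocks, halving both dimensions.

    Both input dimensions must be even; pad with :func:`fit_dimensions`
    first otherwise.  The global mean intensity is preserved exactly.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    if h % 2 or w % 2:
        raise ValueError(f"dimensions {h}x{w} must be even; pad first")
    return img.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def fit_dimensions(img: np.ndarray, levels: int = 3, mode: str = "pad_zero_rows") -> np.ndarray:
    """Make both dimensions multiples of ``2**levels``.

    ``pad_zero_rows`` appends zero rows/columns at the bottom/right up to the
    next multiple (original pixels untouched); ``central_crop`` removes an
    equal number of rows/columns from each side down to the previous
    multiple, taking the odd remainder from the bottom/right.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    m = 2 ** levels
    if mode == "pad_zero_rows":
        nh, nw = -(-h // m) * m, -(-w // m) * m
        out = np.zeros((nh, nw))
        out[:h, :w] = img
        return out
    if mode == "central_crop":
        nh, nw = (h // m) * m, (w // m) * m
        if nh == 0 or nw == 0:
            raise ValueError(f"image {h}x{w} too small to crop to multiples of {m}")
        top, left = (h - nh) // 2, (w - nw) // 2
        return img[top : top + nh, left : left + nw]
    raise ValueError(f"unknown fit mode {mode!r}")


def build_pyramid(img: np.ndarray, levels: int = 3, fit_mode: str = "pad_zero_rows") -> dict[str, np.ndarray]:
    """Build the three-level resolution pyramid {A, A2, A4}.

    Level A is the input unmodified; A2 and A4 are produced by one and two
    2x2 averaging steps (padding an odd dimension with zeros first when
    needed).  Each level is then fitted (``fit_mode``) to multiples of
    ``2**levels`` so a depth-``levels`` packet decomposition decimates to
    integer sizes.
    """
    img = np.asarray(img, dtype=float)
    raw = {"A": img}
    current = img
    for name in ("A2", "A4"):
        h, w = current.shape
        if h % 2 or w % 2:
            padded = np.zeros((h + h % 2, w + w % 2))
            padded[:h, :w] = current
            current = padded
        current = downscale_2x2(current)
        raw[name] = current
    return {name: fit_dimensions(level, levels=levels, mode=fit_mode) for name, level in raw.items()}


def load_image(path: str | Path, grayscale_map: str = "luma601") -> np.ndarray:
    """Read a PNG/BMP/JPEG image as an indexed grayscale matrix."""
    with Image.open(path) as im:
        if im.mode == "L":
            return np.asarray(im, dtype=float)
        arr = np.asarray(im.convert("RGB"), dtype=float)
    return rgb_to_indexed(arr, grayscale_map=grayscale_map)


def load_labeled_images(
    labels_csv: str | Path, grayscale_map: str = "luma601"
) -> list[tuple[np.ndarray, int]]:
    """Load images listed in a ``filename,label`` CSV next to the images.

    Labels ``melanoma`` (positive, 1) and ``nevus``/``dysplastic`` map to the
    binary convention used throughout the pipeline.
    """
    labels_csv = Path(labels_csv)
    root = labels_csv.parent
    out: list[tuple[np.ndarray, int]] = []
    with open(labels_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["label"].strip().lower()
            y = 1 if label == "melanoma" else 0
            out.append((load_image(root / row["filename"], grayscale_map), y))
    if not out:
        raise ValueError(f"no rows in {labels_csv}")
    return out
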