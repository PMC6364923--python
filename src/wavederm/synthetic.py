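"""Synthetic two-class texture generator.

Real dermoscopy collections of melanoma vs. dysplastic-nevus images are hard
to redistribute, so this module generates labeled grayscale textures with the
statistical structure the downstream analysis assumes: the two classes share a
common noise background (and, optionally, a smooth dark lesion-like blob), and
the positive class carries extra noise power confined to an annular band of
the 2-D spatial-frequency plane.  Because the class difference lives at a
known, controllable scale, wavelet-base rankings recovered downstream can be
checked against ground truth.

Frequencies are expressed in cycles/pixel; the Nyquist limit is 0.5.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of a synthetic two-class texture dataset.

    ``effect_size`` is the amplitude of the positive class's band-limited
    excess noise, in units of ``background_sd``; zero makes the two classes
    identically distributed.  The annulus ``band_center +/- band_width/2``
    must lie strictly inside (0, 0.5) cycles/pixel.
    """

    image_height: int = 256
    image_width: int = 256
    n_pos: int = 40
    n_neg: int = 40
    band_center: float = 0.25
    band_width: float = 0.10
    effect_size: float = 3.0
    background_sd: float = 10.0
    lesion_blob: bool = True
    seed: int = 0

    #: mean intensity of the background, 8-bit scale; mid-gray keeps the
    #: band-limited class signal clear of 0/255 saturation, which would
    #: otherwise smear power across the spectrum
    base_level: float = field(default=128.0, repr=False)
    #: peak darkening of the lesion blob, intensity units
    blob_amplitude: float = field(default=60.0, repr=False)

    def validate(self) -> None:
        lo = self.band_center - self.band_width / 2.0
        hi = self.band_center + self.band_width / 2.0
        if not (0.0 < lo and hi < 0.5):
            raise ValueError(
                f"band [{lo:.4f}, {hi:.4f}] must lie strictly inside (0, 0.5) cycles/pixel"
            )
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("images must be at least 8x8")


def _radial_frequency(h: int, w: int) -> np.ndarray:
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    return np.hypot(fy, fx)


def band_mask(h: int, w: int, band_center: float, band_width: float) -> np.ndarray:
    """Boolean annular mask over the 2-D DFT frequency grid."""
    r = _radial_frequency(h, w)
    return (r >= band_center - band_width / 2.0) & (r <= band_center + band_width / 2.0)


def band_power(img: np.ndarray, band_center: float, band_width: float) -> float:
    """Mean spectral power of ``img`` inside the annulus (DC removed).

    Independent of the generator's synthesis route: plain 2-D DFT of the
    zero-mean image, periodogram, mean over the annular bins.
    """
    x = np.asarray(img, dtype=float)
    x = x - x.mean()
    p = np.abs(np.fft.fft2(x)) ** 2 / x.size
    m = band_mask(x.shape[0], x.shape[1], band_center, band_width)
    return float(p[m].mean())


def _band_noise(rng: np.random.Generator, h: int, w: int, mask: np.ndarray) -> np.ndarray:
    """Unit-variance real noise field with power confined to ``mask``."""
    white = rng.standard_normal((h, w))
    spec = np.fft.fft2(white) * mask
    x = np.fft.ifft2(spec).real
    sd = x.std()
    if sd == 0:  # pragma: no cover - mask always has bins by validation
        return x
    return x / sd


def _lesion_blob(h: int, w: int, amplitude: float) -> np.ndarray:
    """Axis-aligned Gaussian-profile darkening centred in the frame."""
    y = (np.arange(h) - (h - 1) / 2.0) / (0.30 * h)
    x = (np.arange(w) - (w - 1) / 2.0) / (0.35 * w)
    return -amplitude * np.exp(-(y[:, None] ** 2 + x[None, :] ** 2))


def make_texture_dataset(spec: TextureSpec) -> list[tuple[np.ndarray, int]]:
    """Generate the dataset described by ``spec``.

    Returns a list of ``(image, label)`` pairs, label 1 for the positive
    (melanoma-like) class and 0 for the negative class, in positive-first
    order.  Images are float arrays clipped to [0, 255].  Fully reproducible
    from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    mask = band_mask(h, w, spec.band_center, spec.band_width)
    blob = _lesion_blob(h, w, spec.blob_amplitude) if spec.lesion_blob else 0.0

    out: list[tuple[np.ndarray, int]] = []
    for label, count in ((1, spec.n_pos), (0, spec.n_neg)):
        for _ in range(count):
            img = spec.base_level + blob + spec.background_sd * rng.standard_normal((h, w))
            # The band carrier is drawn for every image regardless of label so
            # that effect_size = 0 leaves the two classes on one RNG stream
            # with literally identical sampling distributions.
            carrier = _band_noise(rng, h, w, mask)
            if label == 1:
                img = img + spec.effect_size * spec.background_sd * carrier
            out.append((np.clip(img, 0.0, 255.0), label))
    return out


_FIXTURES = ("constant", "impulse", "checkerboard", "ramp")


def make_fixture_image(
    kind: str,
    height: int,
    width: int,
    *,
    value: float = 1.0,
    period: int = 1,
) -> np.ndarray:
    """Deterministic analytic image for transform unit tests.

    ``kind`` is one of ``constant`` (all pixels ``value``), ``impulse``
    (single 1 at the origin), ``checkerboard`` (0/255 tiles of side
    ``period``) or ``ramp`` (left-to-right linear 0..255).
    """
    if kind not in _FIXTURES:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {_FIXTURES}")
    if height < 4 or width < 4 or height % 2 or width % 2:
        raise ValueError("height and width must be even and >= 4")
    if kind == "constant":
        return np.full((height, width), float(value))
    if kind == "impulse":
        img = np.zeros((height, width))
        img[0, 0] = 1.0
        return img
    if kind == "checkerboard":
        y = np.arange(height)[:, None] // period
        x = np.arange(width)[None, :] // period
        return 255.0 * ((y + x) % 2)
    # ramp
    return np.tile(np.linspace(0.0, 255.0, width), (height, 1))


def write_dataset(dataset: list[tuple[np.ndarray, int]], out_dir: str | Path) -> Path:
    """Write images as 8-bit grayscale PNG plus a ``labels.csv`` file.

    The CSV has columns ``filename,label`` with label ``melanoma`` for the
    positive class and ``nevus`` otherwise, so synthetic and real data share
    one loading path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(dataset):
        name = f"img_{i:04d}.png"
        Image.fromarray(np.clip(np.round(img), 0, 255).astype(np.uint8), mode="L").save(out / name)
        rows.append((name, "melanoma" if label == 1 else "nevus"))
    labels_path = out / "labels.csv"
    with open(labels_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        writer.writerows(rows)
    return labels_path
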