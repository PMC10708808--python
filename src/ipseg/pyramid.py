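"""Bicubic upscaling and the inverted input pyramid.

Low-resolution frames are enlarged — never shrunk — with cubic-convolution
(bicubic) interpolation to a ladder of scale factors such as [1, 2, 4].  Each
rung becomes an independent input channel for the multi-scale network, so the
segmenter sees progressively magnified views of the same anatomy.

Conventions (the resampling literature leaves several free choices):

* pixel centers sit at integer coordinates, 0-based, row-major (y=row, x=col);
* destination pixel ``d`` maps to source coordinate ``(d + 0.5)/factor - 0.5``
  (half-pixel centers, the standard resize convention);
* neighbors outside the image are edge-replicated (clamped indices);
* output dimensions are ``round(factor * dim)``.

Interpolated values may overshoot [0, 1] because the cubic kernel has negative
lobes; :func:`build_inverted_pyramid` clamps at build time, while
:func:`upscale` and :func:`interpolate_pixel` return the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

__all__ = [
    "Image",
    "InterpKernelConfig",
    "ScaledImageSet",
    "kernel_weight",
    "interpolate_pixel",
    "upscale",
    "build_inverted_pyramid",
    "read_image",
    "write_image",
]

MIN_DIM = 4  # a 4x4 bicubic neighborhood must exist after border replication


@dataclass(frozen=True)
class InterpKernelConfig:
    """Cubic-convolution kernel hyperparameter (sharpness); -0.5 is standard."""

    a: float = -0.5


@dataclass
class Image:
    """Channel-first pixel array with values in [0, 1].

    ``pixels`` has shape (channels, height, width); grayscale uses 1 channel,
    color 3.
    """

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim == 2:
            p = p[None]
        if p.ndim != 3:
            raise ValueError(f"expected (C,H,W) array, got shape {p.shape}")
        if p.shape[1] < MIN_DIM or p.shape[2] < MIN_DIM:
            raise ValueError(f"image must be at least {MIN_DIM}x{MIN_DIM}, "
                             f"got {p.shape[1]}x{p.shape[2]}")
        if not np.all(np.isfinite(p)):
            raise ValueError("image contains non-finite values")
        self.pixels = p

    @property
    def channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]


@dataclass
class ScaledImageSet:
    """The inverted pyramid: an ordered (scale factor -> image) ladder."""

    entries: list[tuple[float, Image]] = field(default_factory=list)

    def __post_init__(self):
        factors = [f for f, _ in self.entries]
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise ValueError("pyramid factors must be strictly increasing")

    @property
    def factors(self) -> list[float]:
        return [f for f, _ in self.entries]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def kernel_weight(x, cfg: InterpKernelConfig = InterpKernelConfig()):
    """Cubic-convolution weight W(x) for a signed tap distance x.

    Piecewise cubic: (a+2)|x|^3-(a+3)|x|^2+1 for |x|<=1,
    a|x|^3-5a|x|^2+8a|x|-4a for 1<|x|<2, and 0 beyond.  Accepts scalars or
    arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("tap distance must be finite")
    a = cfg.a
    ax = np.abs(x)
    near = (a + 2.0) * ax ** 3 - (a + 3.0) * ax ** 2 + 1.0
    far = a * ax ** 3 - 5.0 * a * ax ** 2 + 8.0 * a * ax - 4.0 * a
    out = np.where(ax <= 1.0, near, np.where(ax < 2.0, far, 0.0))
    return out if out.ndim else float(out)


def interpolate_pixel(src: Image, x: float, y: float,
                      cfg: InterpKernelConfig = InterpKernelConfig()) -> np.ndarray:
    """Bicubic value at source coordinate (x, y); returns one value per channel.

    Sums the 16 neighbors ``Q_ij * W(dy_i) * W(dx_j)`` around the point, with
    edge replication for taps outside the frame.  Values are not clamped.
    """
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("sample coordinates must be finite")
    p = src.pixels
    h, w = src.height, src.width
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    ty, tx = y - y0, x - x0
    rows = np.clip(np.arange(y0 - 1, y0 + 3), 0, h - 1)
    cols = np.clip(np.arange(x0 - 1, x0 + 3), 0, w - 1)
    wy = kernel_weight(np.array([1 + ty, ty, 1 - ty, 2 - ty]), cfg)
    wx = kernel_weight(np.array([1 + tx, tx, 1 - tx, 2 - tx]), cfg)
    patch = p[:, rows[:, None], cols[None, :]]        # (C, 4, 4)
    return np.einsum("chw,h,w->c", patch, wy, wx)


def _axis_taps(in_len: int, out_len: int, cfg: InterpKernelConfig):
    """Per-output-pixel clamped tap indices (out,4) and weights (out,4)."""
    dst = np.arange(out_len, dtype=np.float64)
    src = (dst + 0.5) * (in_len / out_len) - 0.5
    base = np.floor(src).astype(np.intp)
    t = src - base
    offsets = np.array([-1, 0, 1, 2])
    idx = np.clip(base[:, None] + offsets[None, :], 0, in_len - 1)
    dist = np.stack([1 + t, t, 1 - t, 2 - t], axis=1)
    return idx, kernel_weight(dist, cfg)


def upscale(src: Image, factor: float,
            cfg: InterpKernelConfig = InterpKernelConfig()) -> Image:
    """Enlarge an image by ``factor`` (>= 1) with separable bicubic filtering."""
    if not np.isfinite(factor) or factor < 1:
        raise ValueError(f"this pyramid only enlarges; factor {factor} < 1")
    h, w = src.height, src.width
    oh, ow = int(round(factor * h)), int(round(factor * w))
    ridx, rw = _axis_taps(h, oh, cfg)
    cidx, cw = _axis_taps(w, ow, cfg)
    # rows: (C,H,W) -> (C,OH,W); then columns -> (C,OH,OW)
    rows = np.einsum("cohw,oh->cow", src.pixels[:, ridx, :], rw,
                     optimize=True)
    out = np.einsum("cowk,wk->cow", rows[:, :, cidx], cw, optimize=True)
    return Image(out)


def build_inverted_pyramid(src: Image, factors,
                           cfg: InterpKernelConfig = InterpKernelConfig()
                           ) -> ScaledImageSet:
    """Upscale ``src`` to every factor in an ascending ladder starting at 1.

    The factor-1 rung is a bit-identical copy of the source; larger rungs are
    bicubic enlargements clamped to [0, 1].
    """
    factors = list(factors)
    if not factors:
        raise ValueError("factor list must be nonempty")
    if factors[0] != 1:
        raise ValueError("the first pyramid factor must be 1")
    if any(b <= a for a, b in zip(factors, factors[1:])):
        raise ValueError("pyramid factors must be strictly increasing")
    entries: list[tuple[float, Image]] = []
    for f in factors:
        if f == 1:
            entries.append((1.0, Image(src.pixels.copy())))
        else:
            img = upscale(src, f, cfg)
            entries.append((float(f), Image(np.clip(img.pixels, 0.0, 1.0))))
    return ScaledImageSet(entries)


# ----------------------------------------------------------------- image I/O
def read_image(path: str | Path) -> Image:
    """Read a PNG/TIFF as a [0,1] channel-first Image (grayscale or RGB)."""
    with PILImage.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB" if im.mode in ("RGBA", "P", "CMYK") else "L")
        arr = np.asarray(im, dtype=np.float64) / 255.0
    if arr.ndim == 2:
        return Image(arr[None])
    return Image(arr.transpose(2, 0, 1))


def write_image(img: Image | np.ndarray, path: str | Path):
    """Write a [0,1] image (C,H,W) or (H,W) as an 8-bit PNG/TIFF."""
    arr = img.pixels if isinstance(img, Image) else np.asarray(img)
    if arr.ndim == 3:
        arr = arr[0] if arr.shape[0] == 1 else arr.transpose(1, 2, 0)
    q = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    PILImage.fromarray(q).save(path)
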