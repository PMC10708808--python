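"""Echo-like synthetic phantoms: ventricle-shaped masks over speckled frames.

Each phantom emulates a low-resolution (default 112x112) single-channel
echocardiographic frame containing exactly one connected foreground region:
a rotated ellipse, optionally notched into a crescent, standing in for a
left-ventricle cross-section.  The rendered image is

    base intensities (foreground/background)
    + a smooth linear background gradient
    -> Gaussian blur
    -> multiplicative Rayleigh speckle: I * (1 + s * (R - E[R]))
    -> clamp to [0, 1]

Speckle is the granular multiplicative noise characteristic of ultrasound;
a Rayleigh amplitude distribution is the standard first-order model.  The
generator is fully deterministic in its seed and guarantees that every mask
is a single 4-connected component occupying between 3% and 40% of the frame
(redrawing up to 100 times before giving up).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .pyramid import Image, write_image

__all__ = [
    "PhantomParams",
    "PhantomSample",
    "GenerationError",
    "generate_phantom",
    "generate_dataset",
    "load_manifest",
]

FG_FRACTION_BOUNDS = (0.03, 0.40)
_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)  # E[R] for scale-1 Rayleigh noise


class GenerationError(RuntimeError):
    """Raised when no admissible phantom is found within the redraw budget."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and appearance of one phantom draw.

    Lengths are fractions of the frame size unless noted; angles in degrees.
    """

    size: int = 112
    center_jitter: float = 0.08          # max offset of the ellipse center
    semi_axes_range: tuple[float, float] = (0.13, 0.30)
    rotation_range: float = 90.0         # rotation drawn in [-range, +range]
    notch_probability: float = 0.4       # chance of a crescent notch
    notch_depth: float = 0.45            # notch ellipse size vs main ellipse
    speckle_strength: float = 0.35       # multiplicative noise amplitude
    blur_sigma: float = 1.0              # Gaussian blur, pixels
    gradient_amplitude: float = 0.15     # linear background shading
    foreground_intensity: float = 0.75
    background_intensity: float = 0.25

    def __post_init__(self):
        if self.size < 8:
            raise ValueError("frame size must be >= 8")
        lo, hi = self.semi_axes_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("semi-axes range must satisfy 0 < lo <= hi < 0.5")
        if self.speckle_strength < 0 or self.blur_sigma < 0:
            raise ValueError("noise parameters must be nonnegative")
        for v in (self.foreground_intensity, self.background_intensity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("base intensities must lie in [0, 1]")


@dataclass
class PhantomSample:
    image: Image
    mask: np.ndarray                     # (H, W) uint8 in {0, 1}
    seed: int
    params: PhantomParams


def _ellipse_mask(size: int, cy: float, cx: float, sa: float, sb: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / sa) ** 2 + (v / sb) ** 2 <= 1.0


def _draw_mask(rng: np.random.Generator, p: PhantomParams) -> np.ndarray:
    s = p.size
    cy = s / 2 + rng.uniform(-1, 1) * p.center_jitter * s
    cx = s / 2 + rng.uniform(-1, 1) * p.center_jitter * s
    lo, hi = p.semi_axes_range
    sa = rng.uniform(lo, hi) * s
    sb = rng.uniform(lo, hi) * s
    theta = np.deg2rad(rng.uniform(-p.rotation_range, p.rotation_range))
    mask = _ellipse_mask(s, cy, cx, sa, sb, theta)
    if rng.uniform() < p.notch_probability:
        # crescent: carve a smaller ellipse shifted along the major axis
        shift = max(sa, sb) * (1.0 - p.notch_depth / 2)
        ang = theta if sa >= sb else theta + np.pi / 2
        ncy = cy + np.sin(ang) * shift
        ncx = cx + np.cos(ang) * shift
        notch = _ellipse_mask(s, ncy, ncx, sa * p.notch_depth,
                              sb * p.notch_depth, theta)
        mask &= ~notch
    return mask


def _admissible(mask: np.ndarray) -> bool:
    frac = mask.mean()
    if not (FG_FRACTION_BOUNDS[0] <= frac <= FG_FRACTION_BOUNDS[1]):
        return False
    labels, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    return n == 1


def _render(rng: np.random.Generator, mask: np.ndarray,
            p: PhantomParams) -> np.ndarray:
    s = p.size
    img = np.where(mask, p.foreground_intensity, p.background_intensity)
    if p.gradient_amplitude > 0:
        phi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:s, 0:s] / max(s - 1, 1)
        ramp = (yy - 0.5) * np.sin(phi) + (xx - 0.5) * np.cos(phi)
        img = img + p.gradient_amplitude * ramp
    if p.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, p.blur_sigma)
    if p.speckle_strength > 0:
        r = rng.rayleigh(scale=1.0, size=img.shape)
        img = img * (1.0 + p.speckle_strength * (r - _RAYLEIGH_MEAN))
    return np.clip(img, 0.0, 1.0)


def generate_phantom(seed: int, params: PhantomParams = PhantomParams()
                     ) -> PhantomSample:
    """Draw one phantom, fully determined by ``seed`` and ``params``."""
    rng = np.random.default_rng(seed)
    for _ in range(100):
        mask = _draw_mask(rng, params)
        if _admissible(mask):
            break
    else:
        raise GenerationError(
            "no admissible mask in 100 redraws; check PhantomParams")
    img = _render(rng, mask, params)
    return PhantomSample(image=Image(img[None]), mask=mask.astype(np.uint8),
                         seed=seed, params=params)


def _split_assignment(n: int, fractions, rng: np.random.Generator) -> list[str]:
    names = ("train", "val", "test")
    fractions = tuple(fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must be three values summing to 1")
    counts = [int(round(f * n)) for f in fractions]
    counts[0] = n - counts[1] - counts[2]
    order = rng.permutation(n)
    assignment = [""] * n
    pos = 0
    for name, cnt in zip(names, counts):
        for idx in order[pos:pos + cnt]:
            assignment[idx] = name
        pos += cnt
    return assignment


def generate_dataset(n: int, seed: int, out_dir: str | Path,
                     split_fractions=(0.7, 0.2, 0.1),
                     params: PhantomParams = PhantomParams()) -> pd.DataFrame:
    """Write ``n`` PNG image/mask pairs plus a CSV manifest; returns it.

    Manifest columns: ``id,image,mask,split`` with paths relative to
    ``out_dir``.  Both the samples and the split assignment are deterministic
    in ``seed``.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    splits = _split_assignment(n, split_fractions, rng)
    rows = []
    for i in range(n):
        sample = generate_phantom(seed * 1_000_003 + i, params)
        sid = f"phantom_{i:05d}"
        img_rel = f"images/{sid}.png"
        mask_rel = f"masks/{sid}.png"
        write_image(sample.image, out_dir / img_rel)
        write_image(sample.mask.astype(np.float64), out_dir / mask_rel)
        rows.append({"id": sid, "image": img_rel, "mask": mask_rel,
                     "split": splits[i]})
    manifest = pd.DataFrame(rows, columns=["id", "image", "mask", "split"])
    manifest.to_csv(out_dir / "manifest.csv", index=False,
                    quoting=csv.QUOTE_MINIMAL)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV, resolving image/mask paths against its directory."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"id", "image", "mask", "split"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    root = path.parent
    df = df.copy()
    df["image"] = [str(root / p) for p in df["image"]]
    df["mask"] = [str(root / p) for p in df["mask"]]
    return df
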