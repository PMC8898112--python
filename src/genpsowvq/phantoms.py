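"""Synthetic anatomy-like greyscale phantoms.

Stand-ins for the four radiology modalities the codec targets — chest
radiographs, unenhanced brain CT, mammograms and abdominal CT — emulated
at the *statistical* level a block-transform codec cares about: large
piecewise-smooth regions, sharp but band-limited tissue boundaries, a dark
background, and optional additive gaussian noise.  No anatomical fidelity
is intended.

Archetypes
----------
* ``chest``        — thorax ellipse, two dark lung fields, rib arcs and a
  bright mediastinal column.
* ``brain_ct``     — bright skull annulus, brain tissue disc, dark
  ventricle pair.
* ``mammogram``    — breast hemi-disc with a smooth low-frequency glandular
  texture and a cluster of bright specks (calcification-like).
* ``abdominal_ct`` — body ellipse with nested organ ellipses (liver,
  kidneys), a bright vertebral body and aorta.

Structures are low-pass filtered with a gaussian of σ ≈ 2% of the image
side, mimicking the finite point-spread function of real acquisition
systems, before noise is added.  Every phantom is a pure function of its
:class:`PhantomSpec`; image sizes must be multiples of 8 so that wavelet
subbands tile exactly into 8×8 blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["KINDS", "PhantomSpec", "make_phantom", "make_test_suite"]

KINDS = ("chest", "brain_ct", "mammogram", "abdominal_ct")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom: modality archetype, size (H, W) in
    pixels (each a multiple of 8), additive noise level in greylevels,
    and the generator seed."""

    kind: str
    size: tuple[int, int] = (64, 64)
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        h, w = self.size
        if h < 8 or w < 8 or h % 8 or w % 8:
            raise ValueError(
                f"phantom size must be multiples of 8, got {self.size}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.linspace(-1.0, 1.0, h)[:, None]
    x = np.linspace(-1.0, 1.0, w)[None, :]
    return y, x


def _ellipse(y, x, cy, cx, ry, rx, angle: float = 0.0) -> np.ndarray:
    """Boolean mask of an axis-aligned or rotated ellipse in [-1,1]² coords."""
    dy, dx = y - cy, x - cx
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        dy, dx = c * dy - s * dx, s * dy + c * dx
    return (dy / ry) ** 2 + (dx / rx) ** 2 <= 1.0


def _chest(y, x, rng) -> np.ndarray:
    img = np.full(np.broadcast_shapes(y.shape, x.shape), 18.0)
    img[_ellipse(y, x, 0.02, 0.0, 0.80, 0.66)] = 122.0
    img[_ellipse(y, x, 0.02, 0.0, 0.55, 0.14)] = 165.0  # mediastinum
    for side in (-1, 1):
        img[_ellipse(y, x, -0.02, side * 0.36, 0.52, 0.26)] = 48.0
    # rib arcs: thin elliptical annuli clipped to the upper thorax
    thorax = _ellipse(y, x, 0.02, 0.0, 0.78, 0.64)
    for k in range(4):
        r = 0.30 + 0.16 * k
        ring = _ellipse(y, x, 0.55, 0.0, r + 0.035, r * 0.9 + 0.035) \
            & ~_ellipse(y, x, 0.55, 0.0, r - 0.035, r * 0.9 - 0.035)
        img[ring & thorax & (y < 0.25)] = 170.0
    return img


def _brain_ct(y, x, rng) -> np.ndarray:
    img = np.full(np.broadcast_shapes(y.shape, x.shape), 8.0)
    skull = _ellipse(y, x, 0.0, 0.0, 0.80, 0.68)
    inner = _ellipse(y, x, 0.0, 0.0, 0.68, 0.56)
    img[skull] = 235.0
    img[inner] = 98.0
    for side in (-1, 1):
        img[_ellipse(y, x, -0.08, side * 0.16, 0.26, 0.10,
                     angle=side * 0.35)] = 42.0  # lateral ventricles
    img[_ellipse(y, x, 0.38, 0.0, 0.10, 0.06)] = 60.0  # fourth ventricle
    return img


def _mammogram(y, x, rng) -> np.ndarray:
    shape = np.broadcast_shapes(y.shape, x.shape)
    img = np.full(shape, 12.0)
    r = np.sqrt((y / 0.72) ** 2 + ((x + 0.22) / 0.68) ** 2)
    breast = r <= 1.0
    base = 162.0 - 55.0 * r  # smooth falloff toward the skin line
    # glandular texture: strongly low-passed noise, deterministic per seed
    tex = gaussian_filter(rng.normal(0.0, 1.0, shape),
                          sigma=max(2.0, shape[0] / 12))
    tex *= 12.0 / max(tex.std(), 1e-12)
    img[breast] = (base + tex)[breast]
    # cluster of bright specks
    for _ in range(6):
        cy = rng.uniform(-0.30, 0.10)
        cx = rng.uniform(-0.45, -0.05)
        img[_ellipse(y, x, cy, cx, 0.035, 0.035)] = 232.0
    return img


def _abdominal_ct(y, x, rng) -> np.ndarray:
    img = np.full(np.broadcast_shapes(y.shape, x.shape), 14.0)
    img[_ellipse(y, x, 0.0, 0.0, 0.62, 0.82)] = 108.0     # body
    img[_ellipse(y, x, -0.12, 0.30, 0.34, 0.38)] = 140.0  # liver
    img[_ellipse(y, x, -0.05, -0.42, 0.24, 0.22)] = 72.0  # stomach/bowel gas
    for side in (-1, 1):
        img[_ellipse(y, x, 0.30, side * 0.36, 0.14, 0.10)] = 125.0  # kidneys
    img[_ellipse(y, x, 0.38, 0.0, 0.13, 0.11)] = 215.0    # vertebral body
    img[_ellipse(y, x, 0.18, -0.06, 0.05, 0.05)] = 170.0  # aorta
    return img


_BUILDERS = {
    "chest": _chest,
    "brain_ct": _brain_ct,
    "mammogram": _mammogram,
    "abdominal_ct": _abdominal_ct,
}


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom as an (H, W) uint8 image.

    The structural content depends only on ``(kind, size, seed)``; the
    noise field only on ``(size, seed)`` — so the same spec at two noise
    levels shares its anatomy.
    """
    spec.validate()
    h, w = spec.size
    y, x = _grid(h, w)
    rng_structure = np.random.default_rng([spec.seed, 0])
    rng_noise = np.random.default_rng([spec.seed, 1])
    img = _BUILDERS[spec.kind](y, x, rng_structure)
    img = gaussian_filter(img, sigma=0.02 * min(h, w))
    if spec.noise_sd > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def make_test_suite(n_per_kind: int, size: tuple[int, int] = (64, 64),
                    seed: int = 0, noise_sd: float = 2.0
                    ) -> list[tuple[PhantomSpec, np.ndarray]]:
    """Reproducible corpus of ``4·n_per_kind`` phantoms covering all kinds."""
    if n_per_kind < 1:
        raise ValueError("n_per_kind must be >= 1")
    rng = np.random.default_rng(seed)
    suite = []
    for kind in KINDS:
        for _ in range(n_per_kind):
            s = PhantomSpec(kind=kind, size=size, noise_sd=noise_sd,
                            seed=int(rng.integers(2**31)))
            suite.append((s, make_phantom(s)))
    return suite
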