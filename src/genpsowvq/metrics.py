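"""Image-quality and rate metrics for 8-bit greyscale codecs.

All measures operate on two equally sized greyscale images: the original
``f`` and the reconstruction ``g``, with pixel values on the integer range
[0, 255].  Computation is carried out in double precision after casting the
integer pixels to reals.

The distortion measures are the classical ones:

* ``mse``   — mean squared error over all ``n = H·W`` pixels,
* ``rmse``  — its square root,
* ``psnr``  — ``10·log10(255² / MSE)`` in dB (``inf`` for a lossless pair),
* ``ssim``  — structural similarity with stabilizers ``c1 = (0.01·255)²``,
  ``c2 = (0.03·255)²``, computed by default from *global* image statistics
  (a single window covering the whole image); an optional sliding-window
  mode averages local SSIM over dense 8×8 windows,
* ``snr``   — signal power over error power, ``10·log10(ΣY² / Σ(Ŷ−Y)²)`` dB,
* ``nmse``  — MSE normalized by the mean squared signal, ``MSE / mean(Y²)``.

The rate measure ``compression_ratio`` is the compressed size as a
percentage of the original size, so 25% means a 4:1 reduction and smaller
values mean stronger compression.

Lossless pairs (MSE = 0) yield ``float('inf')`` for PSNR and SNR rather
than raising, so batch evaluation never aborts on an identity round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "QualityReport",
    "mse",
    "rmse",
    "psnr",
    "ssim",
    "snr",
    "nmse",
    "compression_ratio",
    "quality_report",
]

#: SSIM stabilizing constants for an 8-bit dynamic range L = 255.
SSIM_C1 = (0.01 * 255.0) ** 2
SSIM_C2 = (0.03 * 255.0) ** 2


def _as_float_pair(original, reconstructed) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(original, dtype=np.float64)
    b = np.asarray(reconstructed, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("images must be 2-D greyscale arrays")
    if a.shape != b.shape:
        raise ValueError(
            f"image dimensions differ: {a.shape} vs {b.shape}"
        )
    return a, b


@dataclass(frozen=True)
class QualityReport:
    """Aggregate of the six codec evaluation measures.

    ``psnr_db`` and ``snr_db`` are ``float('inf')`` for a lossless pair.
    ``cr_percent`` is the bitstream size as a percentage of the raw
    8-bit image size.
    """

    psnr_db: float
    ssim: float
    mse: float
    rmse: float
    snr_db: float
    nmse: float
    cr_percent: float

    def to_dict(self) -> dict:
        """Plain dict with ``inf`` serialized as the string ``"inf"``."""
        d = asdict(self)
        return {k: ("inf" if math.isinf(v) else v) for k, v in d.items()}


def mse(original, reconstructed) -> float:
    """Mean squared error between two equally sized greyscale images."""
    a, b = _as_float_pair(original, reconstructed)
    d = b - a
    return float(np.mean(d * d))


def rmse(original, reconstructed) -> float:
    """Root mean squared error, ``sqrt(mse)``."""
    return math.sqrt(mse(original, reconstructed))


def psnr(original, reconstructed) -> float:
    """Peak signal-to-noise ratio in dB for 8-bit images.

    Returns ``float('inf')`` when the images are identical.
    """
    m = mse(original, reconstructed)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / m)


def ssim(original, reconstructed, *, windowed: bool = False,
         window: int = 8) -> float:
    """Structural similarity index in [-1, 1].

    By default the statistics (means, variances, covariance) are taken over
    the whole image — a single global window.  With ``windowed=True`` the
    index is instead the mean of local SSIM values over all dense
    ``window``×``window`` patches (stride 1), the common sliding-window
    practice.  Variances and the covariance use the population
    (divide-by-n) convention in both modes.
    """
    a, b = _as_float_pair(original, reconstructed)
    if windowed:
        return _ssim_windowed(a, b, window)
    mu_a = a.mean()
    mu_b = b.mean()
    var_a = a.var()
    var_b = b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    num = (2.0 * mu_a * mu_b + SSIM_C1) * (2.0 * cov + SSIM_C2)
    den = (mu_a**2 + mu_b**2 + SSIM_C1) * (var_a + var_b + SSIM_C2)
    return float(num / den)


def _ssim_windowed(a: np.ndarray, b: np.ndarray, window: int) -> float:
    if min(a.shape) < window:
        raise ValueError("image smaller than the SSIM window")
    # uniform_filter computes local means; restrict to windows fully inside.
    half = window // 2
    sl = tuple(
        slice(half, half + n - window + 1) for n in a.shape
    )
    mu_a = uniform_filter(a, window)[sl]
    mu_b = uniform_filter(b, window)[sl]
    mu_aa = uniform_filter(a * a, window)[sl]
    mu_bb = uniform_filter(b * b, window)[sl]
    mu_ab = uniform_filter(a * b, window)[sl]
    var_a = mu_aa - mu_a**2
    var_b = mu_bb - mu_b**2
    cov = mu_ab - mu_a * mu_b
    num = (2 * mu_a * mu_b + SSIM_C1) * (2 * cov + SSIM_C2)
    den = (mu_a**2 + mu_b**2 + SSIM_C1) * (var_a + var_b + SSIM_C2)
    return float(np.mean(num / den))


def snr(original, reconstructed) -> float:
    """Signal-to-noise ratio ``10·log10(ΣY² / Σ(Ŷ−Y)²)`` in dB.

    The original must carry non-zero signal; returns ``inf`` on zero error.
    """
    a, b = _as_float_pair(original, reconstructed)
    sig = float(np.sum(a * a))
    if sig == 0.0:
        raise ValueError("SNR undefined for an all-zero original image")
    err = float(np.sum((b - a) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(sig / err)


def nmse(original, reconstructed) -> float:
    """Normalized MSE: ``MSE / mean(Y²)`` with Y the original image."""
    a, b = _as_float_pair(original, reconstructed)
    sig = float(np.mean(a * a))
    if sig == 0.0:
        raise ValueError("NMSE undefined for an all-zero original image")
    return mse(a, b) / sig


def compression_ratio(original_bits: int, compressed_bits: int) -> float:
    """Compressed size as a percentage of the original size.

    25.0 means the stream is a quarter of the raw image (4:1 reduction).
    """
    if original_bits <= 0 or compressed_bits <= 0:
        raise ValueError("bit counts must be positive")
    return 100.0 * compressed_bits / original_bits


def quality_report(original, reconstructed, stream_bits: int) -> QualityReport:
    """Evaluate all metrics for one original/reconstruction pair.

    ``stream_bits`` is the serialized size of the compressed representation;
    the raw size is taken as 8 bits per pixel.
    """
    a, b = _as_float_pair(original, reconstructed)
    raw_bits = 8 * a.size
    return QualityReport(
        psnr_db=psnr(a, b),
        ssim=ssim(a, b),
        mse=mse(a, b),
        rmse=rmse(a, b),
        snr_db=snr(a, b),
        nmse=nmse(a, b),
        cr_percent=compression_ratio(raw_bits, stream_bits),
    )
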