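"""Wavelet decomposition, 8×8 block tiling, and pixel↔real normalization.

The codec front end turns a greyscale image into a set of coefficient
planes (one approximation plane plus horizontal/vertical/diagonal detail
triples per level), normalizes each plane to [0, 1], and tiles it into
8×8 blocks flattened in raster order — the 64-component vectors the
compressor network consumes.  Every step here is exactly invertible
before quantization.

The transform is the separable 2-D DWT with periodic ("periodization")
boundary extension, which keeps the orthonormal families (haar, db2, db4)
energy preserving and the subband sizes exactly halved for even
dimensions.  Tiling pads with edge replication when a plane dimension is
not a multiple of the block size; untiling discards the padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "SubbandSet",
    "BlockSet",
    "dwt2",
    "idwt2",
    "tile_blocks",
    "untile_blocks",
    "normalize",
    "denormalize",
    "SUPPORTED_FAMILIES",
]

#: Wavelet families the codec accepts (all orthonormal, so the transform
#: preserves energy under periodization).
SUPPORTED_FAMILIES = ("haar", "db2", "db4")

_MODE = "periodization"


@dataclass
class SubbandSet:
    """A multi-level 2-D wavelet decomposition of one image plane.

    ``details[k]`` is the (horizontal, vertical, diagonal) triple of the
    k-th level counted from the *coarsest* scale, matching the coefficient
    order of a multilevel separable DWT.
    """

    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    level: int
    family: str
    original_dims: tuple[int, int]

    def planes(self) -> list[np.ndarray]:
        """All coefficient planes, approximation first, then cH, cV, cD
        per level from coarse to fine."""
        out = [self.approximation]
        for triple in self.details:
            out.extend(triple)
        return out


@dataclass
class BlockSet:
    """8×8 blocks of one coefficient plane, flattened in raster order.

    ``blocks`` is an (n_blocks, block_size²) array; block ``r·cols + c``
    covers rows ``[8r, 8r+8)`` and columns ``[8c, 8c+8)`` of the padded
    plane.  ``source_dims`` are the dimensions of the unpadded plane so
    the tiling can be undone exactly.
    """

    blocks: np.ndarray
    grid_dims: tuple[int, int]
    source_dims: tuple[int, int]
    block_size: int = 8
    pad_value: float = field(default=float("nan"))  # informational only


def dwt2(image, level: int = 1, family: str = "haar") -> SubbandSet:
    """Separable 2-D wavelet decomposition of a greyscale plane.

    Parameters
    ----------
    image : array-like, shape (H, W)
        Pixel or coefficient plane; cast to float64.
    level : int
        Decomposition depth; each image axis must be at least ``2**level``.
    family : str
        One of ``haar``, ``db2``, ``db4``.
    """
    a = np.asarray(image, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("dwt2 expects a 2-D plane")
    if family not in SUPPORTED_FAMILIES:
        raise ValueError(f"unsupported wavelet family {family!r}")
    if level < 1:
        raise ValueError("level must be >= 1")
    if min(a.shape) < 2**level:
        raise ValueError(
            f"image of shape {a.shape} too small for a {level}-level transform"
        )
    coeffs = pywt.wavedec2(a, family, mode=_MODE, level=level)
    approx = coeffs[0]
    details = [tuple(np.asarray(p) for p in triple) for triple in coeffs[1:]]
    return SubbandSet(
        approximation=np.asarray(approx),
        details=details,
        level=level,
        family=family,
        original_dims=(a.shape[0], a.shape[1]),
    )


def idwt2(subbands: SubbandSet) -> np.ndarray:
    """Inverse of :func:`dwt2`; returns a plane of ``original_dims``."""
    if len(subbands.details) != subbands.level:
        raise ValueError("number of detail triples must equal the level")
    coeffs = [subbands.approximation] + [
        tuple(triple) for triple in subbands.details
    ]
    plane = pywt.waverec2(coeffs, subbands.family, mode=_MODE)
    h, w = subbands.original_dims
    # periodization may round odd sizes up; crop back.
    return np.asarray(plane)[:h, :w]


def tile_blocks(plane, block_size: int = 8) -> BlockSet:
    """Tile a plane into raster-ordered flattened blocks.

    Planes whose dimensions are not multiples of ``block_size`` are padded
    by replicating the last row/column (edge padding), which avoids the
    artificial high-frequency content zero padding would inject.
    """
    a = np.asarray(plane, dtype=np.float64)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("tile_blocks expects a non-empty 2-D plane")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    h, w = a.shape
    rows = -(-h // block_size)
    cols = -(-w // block_size)
    padded = np.pad(
        a, ((0, rows * block_size - h), (0, cols * block_size - w)),
        mode="edge",
    )
    blocks = (
        padded.reshape(rows, block_size, cols, block_size)
        .transpose(0, 2, 1, 3)
        .reshape(rows * cols, block_size * block_size)
    )
    return BlockSet(
        blocks=blocks,
        grid_dims=(rows, cols),
        source_dims=(h, w),
        block_size=block_size,
    )


def untile_blocks(blockset: BlockSet) -> np.ndarray:
    """Reassemble the plane from a :class:`BlockSet`, dropping padding."""
    rows, cols = blockset.grid_dims
    bs = blockset.block_size
    blocks = np.asarray(blockset.blocks, dtype=np.float64)
    if blocks.shape != (rows * cols, bs * bs):
        raise ValueError(
            f"blocks of shape {blocks.shape} inconsistent with grid "
            f"{blockset.grid_dims} and block size {bs}"
        )
    padded = (
        blocks.reshape(rows, cols, bs, bs)
        .transpose(0, 2, 1, 3)
        .reshape(rows * bs, cols * bs)
    )
    h, w = blockset.source_dims
    return padded[:h, :w]


def normalize(values, lo: float, hi: float) -> np.ndarray:
    """Affine map of ``values`` from [lo, hi] onto [0, 1], clipped."""
    if not hi > lo:
        raise ValueError("normalize requires hi > lo")
    a = np.asarray(values, dtype=np.float64)
    return np.clip((a - lo) / (hi - lo), 0.0, 1.0)


def denormalize(values, lo: float, hi: float,
                round_to_int: bool = False) -> np.ndarray:
    """Inverse of :func:`normalize`.

    With ``round_to_int=True`` the result is rounded half-up to the nearest
    integer, as needed when mapping back to the pixel lattice.
    """
    if not hi > lo:
        raise ValueError("denormalize requires hi > lo")
    a = np.asarray(values, dtype=np.float64) * (hi - lo) + lo
    if round_to_int:
        a = np.floor(a + 0.5)
    return a
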