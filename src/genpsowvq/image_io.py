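"""Reading and writing 8-bit greyscale images (PNG and binary PGM).

Thin wrappers over imageio/Pillow that enforce the codec's input contract:
2-D uint8 arrays.  RGB images whose channels are identical are accepted
and collapsed to one channel; anything genuinely multi-channel is
rejected rather than silently converted.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["read_image", "write_image"]


def read_image(path) -> np.ndarray:
    """Load a greyscale image as a 2-D uint8 array."""
    a = np.asarray(iio.imread(path))
    if a.ndim == 3:
        if a.shape[2] == 4:
            a = a[:, :, :3]
        if a.shape[2] == 1 or np.all(a[:, :, :1] == a):
            a = a[:, :, 0]
        else:
            raise ValueError(f"{path} is not a greyscale image")
    if a.ndim != 2:
        raise ValueError(f"{path} is not a 2-D image")
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.integer) and a.max() <= 255 and a.min() >= 0:
            a = a.astype(np.uint8)
        else:
            raise ValueError(f"{path} is not an 8-bit image")
    return a


def write_image(path, image) -> None:
    """Write a 2-D uint8 array as PNG or binary PGM, by file extension."""
    a = np.asarray(image)
    if a.ndim != 2 or a.dtype != np.uint8:
        raise ValueError("write_image expects a 2-D uint8 array")
    iio.imwrite(path, a)
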