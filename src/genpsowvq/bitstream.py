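"""Self-contained binary container for compressed images (.gwq).

The decoder needs nothing outside the stream: the header carries the image
geometry, the wavelet configuration, the output layer of the compressor
network, the VQ codebook and the per-plane normalization constants; the
payload is the packed codeword indices, ``log2(K)`` bits each, big-endian
bit order within bytes, zero-padded to a byte boundary per plane.

To keep small images below 100% compression ratio the header stores the
decoder weights as little-endian float16 and the codewords (which live in
the sigmoid range (0, 1)) as uint8 fixed point against a float32
min/max pair; the model file keeps full float32 precision.  The exact byte
layout is documented in docs/FORMAT.md.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = ["MAGIC", "PlanePayload", "Bitstream", "FormatError",
           "pack_indices", "unpack_indices"]

MAGIC = b"GWQ1"
VERSION = 1

FAMILY_IDS = {"haar": 0, "db2": 1, "db4": 2}
FAMILY_NAMES = {v: k for k, v in FAMILY_IDS.items()}


class FormatError(ValueError):
    """Raised when a stream is corrupt or truncated; carries the byte
    offset at which parsing failed."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


def pack_indices(indices: np.ndarray, bitwidth: int) -> bytes:
    """Pack integer indices MSB-first into bytes, zero-padded at the end."""
    idx = np.asarray(indices, dtype=np.int64)
    if idx.size == 0:
        return b""
    shifts = np.arange(bitwidth - 1, -1, -1)
    bits = ((idx[:, None] >> shifts) & 1).astype(np.uint8).ravel()
    return np.packbits(bits).tobytes()


def unpack_indices(payload: bytes, count: int, bitwidth: int) -> np.ndarray:
    """Inverse of :func:`pack_indices` for a known index count."""
    need = -(-count * bitwidth // 8)
    if len(payload) < need:
        raise ValueError("payload shorter than the declared index count")
    bits = np.unpackbits(np.frombuffer(payload[:need], dtype=np.uint8))
    bits = bits[: count * bitwidth].reshape(count, bitwidth).astype(np.int64)
    weights = 1 << np.arange(bitwidth - 1, -1, -1)
    return bits @ weights


@dataclass
class PlanePayload:
    """Per-coefficient-plane record: geometry, normalization range and the
    codeword index per 8×8 block (raster order)."""

    plane_dims: tuple[int, int]
    grid_dims: tuple[int, int]
    lo: float
    hi: float
    indices: np.ndarray

    @property
    def n_blocks(self) -> int:
        return int(self.grid_dims[0] * self.grid_dims[1])


@dataclass
class Bitstream:
    """Parsed (or to-be-serialized) compressed representation."""

    height: int
    width: int
    family: str
    level: int
    n_hidden: int
    K: int
    recurrent: bool
    w_out: np.ndarray       # (H, 64) — stored as float16
    b_out: np.ndarray       # (64,)   — stored as float16
    codebook: np.ndarray    # (K, H)  — stored as uint8 fixed point
    planes: list[PlanePayload]

    @property
    def bitwidth(self) -> int:
        return max(1, self.K.bit_length() - 1) if self.K > 1 else 1

    @property
    def payload_bits(self) -> int:
        """Index bits only: Σ_plane n_blocks · log2(K)."""
        return sum(p.n_blocks * self.bitwidth for p in self.planes)

    def predicted_bits(self) -> int:
        """Exact serialized size in bits, computed from the metadata."""
        header = (
            len(MAGIC) + 1 + 1            # magic, version, flags
            + 2 + 2 + 1 + 1 + 1 + 1 + 2   # H, W, family, level, n_hidden, b, n_planes
            + 2 * self.w_out.size + 2 * self.b_out.size
            + 4 + 4 + self.codebook.size  # codebook lo/hi + uint8 words
        )
        per_plane = sum(
            16 + -(-p.n_blocks * self.bitwidth // 8) for p in self.planes
        )
        return 8 * (header + per_plane)

    # -- serialization --------------------------------------------------

    def to_bytes(self) -> bytes:
        out = bytearray()
        out += MAGIC
        out += struct.pack("<BB", VERSION, 1 if self.recurrent else 0)
        out += struct.pack("<HH", self.height, self.width)
        out += struct.pack("<BBBB", FAMILY_IDS[self.family], self.level,
                           self.n_hidden, self.bitwidth)
        out += struct.pack("<H", len(self.planes))
        out += np.asarray(self.w_out, dtype="<f2").tobytes()
        out += np.asarray(self.b_out, dtype="<f2").tobytes()
        cb = np.asarray(self.codebook, dtype=np.float64)
        cb_lo = float(cb.min())
        cb_hi = float(cb.max())
        scale = (cb_hi - cb_lo) or 1.0
        q = np.floor((cb - cb_lo) / scale * 255.0 + 0.5).astype(np.uint8)
        out += struct.pack("<ff", cb_lo, cb_hi)
        out += q.tobytes()
        for p in self.planes:
            out += struct.pack("<HHHH", p.plane_dims[0], p.plane_dims[1],
                               p.grid_dims[0], p.grid_dims[1])
            out += struct.pack("<ff", p.lo, p.hi)
            out += pack_indices(p.indices, self.bitwidth)
        return bytes(out)

    @classmethod
    def from_bytes(cls, data: bytes) -> "Bitstream":
        pos = 0

        def take(n: int, what: str) -> bytes:
            nonlocal pos
            if pos + n > len(data):
                raise FormatError(f"truncated stream while reading {what}", pos)
            chunk = data[pos:pos + n]
            pos += n
            return chunk

        if take(4, "magic") != MAGIC:
            raise FormatError("bad magic; not a GWQ1 stream", 0)
        version, flags = struct.unpack("<BB", take(2, "version"))
        if version != VERSION:
            raise FormatError(f"unsupported version {version}", 4)
        height, width = struct.unpack("<HH", take(4, "dimensions"))
        fam_id, level, n_hidden, bitwidth = struct.unpack(
            "<BBBB", take(4, "configuration"))
        if fam_id not in FAMILY_NAMES:
            raise FormatError(f"unknown wavelet family id {fam_id}", pos - 4)
        (n_planes,) = struct.unpack("<H", take(2, "plane count"))
        h = n_hidden
        w_out = np.frombuffer(take(2 * h * 64, "decoder weights"),
                              dtype="<f2").astype(np.float64).reshape(h, 64)
        b_out = np.frombuffer(take(2 * 64, "decoder biases"),
                              dtype="<f2").astype(np.float64)
        K = 1 << bitwidth
        cb_lo, cb_hi = struct.unpack("<ff", take(8, "codebook range"))
        q = np.frombuffer(take(K * h, "codebook"), dtype=np.uint8)
        scale = (cb_hi - cb_lo) or 1.0
        codebook = (q.astype(np.float64) / 255.0 * scale + cb_lo).reshape(K, h)
        planes: list[PlanePayload] = []
        for _ in range(n_planes):
            ph, pw, gr, gc = struct.unpack("<HHHH", take(8, "plane geometry"))
            lo, hi = struct.unpack("<ff", take(8, "plane range"))
            n_blocks = gr * gc
            nbytes = -(-n_blocks * bitwidth // 8)
            idx = unpack_indices(take(nbytes, "plane indices"),
                                 n_blocks, bitwidth)
            planes.append(PlanePayload(plane_dims=(ph, pw),
                                       grid_dims=(gr, gc),
                                       lo=lo, hi=hi, indices=idx))
        return cls(height=height, width=width,
                   family=FAMILY_NAMES[fam_id], level=level,
                   n_hidden=n_hidden, K=K, recurrent=bool(flags & 1),
                   w_out=w_out, b_out=b_out, codebook=codebook,
                   planes=planes)
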