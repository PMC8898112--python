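# File formats

## `.gwq` compressed bitstream

Self-contained: a decoder needs nothing outside the stream. All
multi-byte integers and floats are little-endian; index packing inside the
payload is MSB-first within each byte.

| offset | size | field |
|---|---|---|
| 0 | 4 | magic `"GWQ1"` |
| 4 | 1 | version (`1`) |
| 5 | 1 | flags (bit 0: recurrent context was enabled at encode time) |
| 6 | 2 | image height H (u16) |
| 8 | 2 | image width W (u16) |
| 10 | 1 | wavelet family id (0 = haar, 1 = db2, 2 = db4) |
| 11 | 1 | decomposition level L |
| 12 | 1 | hidden width H_net |
| 13 | 1 | index bit-width b (codebook size K = 2^b) |
| 14 | 2 | plane count (u16, must equal 1 + 3·L) |
| 16 | 2·H_net·64 | decoder weights `w_out`, float16, row-major (H_net × 64) |
| … | 2·64 | decoder biases `b_out`, float16 |
| … | 4 + 4 | codebook range `cb_lo`, `cb_hi` (float32) |
| … | K·H_net | codewords, uint8 fixed point: `value = q/255·(cb_hi−cb_lo) + cb_lo` |

Then, per coefficient plane in the order *approximation, then (cH, cV, cD)
per level from coarse to fine*:

| size | field |
|---|---|
| 2 + 2 | plane height, width (u16) — unpadded subband dimensions |
| 2 + 2 | tiling grid rows, cols (u16) |
| 4 + 4 | normalization range `lo`, `hi` (float32) |
| ceil(rows·cols·b / 8) | packed codeword indices, raster order, MSB-first, zero-padded to a byte boundary |

The payload bit count is exactly `Σ_plane rows·cols·b`;
`Bitstream.predicted_bits()` reproduces the total serialized size in bits
from the metadata alone and is asserted against the real byte count in the
tests.

The decoder weights travel at reduced precision (float16 weights, uint8
codewords) so that small images stay below 100% compression ratio; the
reconstruction is *defined* by these quantized values — decoding an
in-memory `Bitstream` object first canonicalizes it through serialization
so bytes and object decode identically.

## `.gwm` model file

JSON with magic `"GWM1"`: wavelet family/level, block size, seed, network
shape (`n_hidden`, `recurrent`) and all parameters (`w_in`, `b_hidden`,
optional `w_rec`, `w_out`, `b_out`) plus the codebook, each stored as a
flat list of float32 values. Saving a loaded model reproduces the file
byte-for-byte.
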