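# Methods

## The codec in one paragraph

GenPSOWVQ is a lossy codec for 8-bit greyscale medical images. An image
is decomposed by a separable 2-D wavelet transform; every coefficient
plane is affinely normalized to [0, 1] and tiled into 8×8 blocks; each
block, flattened to a 64-vector, is mapped by a trained 64–H–64 logistic
autoencoder to an H-dimensional hidden code; the code is vector-quantized
against a K-word codebook and only the codeword index — log2(K) bits per
block — travels in the bitstream, together with a self-contained header
(decoder layer, codebook, per-plane normalization constants). Both the
network weights and the codebook are trained by a hybrid derivative-free
optimizer: a genetic-algorithm phase whose final population seeds a
particle-swarm phase (GenPSO). No gradients are used anywhere.

## Model components and conventions

**Wavelet front end.** Default 1-level `haar` (configurable `db2`/`db4`,
levels 1–3), periodic boundary extension, so the transform is orthonormal:
coefficient energy equals pixel energy and squared errors in coefficient
space map one-to-one onto pixel MSE. Plane order is approximation first,
then (cH, cV, cD) per level from coarse to fine.

**Normalization.** The approximation plane is mapped by its own
(min, max); detail planes symmetrically by (−m, m) with m the largest
coefficient magnitude (so a zero coefficient always maps to 0.5). The
constants are per image and per plane and travel in the header. Degenerate
ranges (constant planes) fall back to a unit range.

**Tiling.** Row-major 8×8 blocks, top-left origin; planes whose
dimensions are not multiples of 8 are padded by edge replication and the
padding is discarded on reassembly. Tiling and the transform round-trip
losslessly (≤1e-9) before quantization — every bit of loss is introduced
by the network and the quantizer.

**Compressor network.** 64 inputs, H ∈ {2, 4, 8, 16, 32, 64} hidden and
64 output units, logistic sigmoid on both layers (inputs and outputs live
in [0, 1]). An optional Elman-style context matrix feeds the previous
block's hidden state back into the current one; it is ON by default but
OFF in the evaluation recipe (below). Parameters flatten in the fixed
order `w_in, b_hidden, [w_rec,] w_out, b_out`, which is the genome layout
the optimizer manipulates.

**Vector quantizer.** K = 2^b codewords of dimension H over the hidden
space; assignment is nearest-euclidean with ties broken to the lowest
index (deterministic across platforms). The training objective is the
usual mean squared distance to the nearest codeword.

**Bitstream.** See `FORMAT.md`. Decoder weights are serialized as
float16 and codewords as uint8 fixed point: with float32 fields the header
of a 64×64 stream (H=16, K=64) would already exceed the raw image, making
a sub-100% compression ratio impossible for a self-contained stream. The
model file (`.gwm`) keeps float32. Reconstruction is defined by the
quantized header: decoding an in-memory stream object canonicalizes it
through serialization first. Reconstructed pixels are clipped to [0, 255]
and rounded half-up.

## The GenPSO optimizer

GA phase, per generation with population μ (default 50): μ offspring are
bred by *node crossover* — one node (a hidden or output unit, or one
codeword) is drawn uniformly and its complete incoming slice (weights plus
bias) is swapped between two uniformly chosen distinct parents — followed
by per-gene gaussian mutation (rate 0.05, scale 0.1 by default). Parents
and offspring are randomly mixed; each individual then meets
round(0.1·2μ) distinct random opponents and scores a win per opponent
with worse fitness; the μ individuals with the most wins survive (ties by
fitness, then stable order). Elitism (default on) re-injects the
incumbent best if selection lost it, which makes the best-fitness history
non-increasing. The phase stops when the best fitness has a range below
1e-5 over the last 50 generations (window, tolerance and a
successive-delta variant are configurable) or at a 500-generation cap.

PSO phase: particles start exactly at the GA's final genomes with zero
velocity; per iteration `v ← w·v + c1·r1∘(pbest−x) + c2·r2∘(gbest−x)`,
`x ← x + v`, with w = 0.729, c1 = c2 = 1.49445 (standard
constriction-equivalent values), per-coordinate uniform r1, r2, and a ±1
per-coordinate velocity clamp (configurable) to bound divergence.
pbest/gbest update on strict improvement; gbest is stored as a copy. The
phase stops when gbest falls below a tolerance or at an iteration cap.
The hybrid returns the better of the two phases' bests.

A run is a pure function of (objective, config): one seeded generator
drives every random draw, objective evaluations are counted, and reruns
are bit-identical. Non-finite objective values raise immediately.

**Codebook search.** The genome is the K·H concatenation of codewords and
node crossover swaps whole codewords. The GA's initial population is
seeded half with random K-subsets of the training vectors (so an exact
cover is present whenever one exists, and the elitist GA can never return
anything worse) and half with uniform codebooks over the data bounding
box; explicit candidates (e.g. a smaller codebook padded with duplicates)
can be injected, which yields the monotone-capacity guarantee tested in
the suite.

## Training recipes

`train(images, config)` pools the normalized blocks of all images, runs
GenPSO on the network genome against the mean squared block-autoencoding
error, encodes all blocks, then runs GenPSO on the codebook genome
against VQ distortion. `CodecConfig.for_small_corpus(n_hidden, K, seed)`
is the recipe used by the tests, the examples and the acceptance script:
feed-forward variant (no context), network search with population 50, GA
capped at 60 generations (stagnation window 30) handing a still-diverse
population to a 2000-iteration PSO with velocity clamp 0.2; codebook
search with population 50, GA ≤60, PSO 300. One model trains in roughly
half a minute to a minute on one CPU for eight 64×64 images. The context
matrix is disabled in this recipe because raster-adjacent blocks of tiled
wavelet planes carry little exploitable sequential structure, the
derivative-free budget is better spent on the feed-forward weights, and
the feed-forward variant doubles as the plain-FFNN self-comparison
baseline.

## The phantom generator

Real chest radiographs, brain CTs, mammograms and abdominal CTs cannot be
shipped with the package, so `phantoms` generates seeded stand-ins that
emulate what a block-transform codec is sensitive to: large
piecewise-smooth regions, band-limited boundaries (structures are blurred
with a gaussian of σ = 2% of the image side, mimicking an acquisition
PSF), a dark background, and additive gaussian noise (default sd 2
greylevels, a mild level typical of 8-bit exported radiology images).
Per archetype: thorax + lung fields + rib arcs; skull annulus + ventricle
pair; breast disc with low-frequency glandular texture and bright specks;
nested abdominal organ ellipses with a bright vertebral body. They do
**not** emulate anatomical variability, modality-specific noise spectra
(quantum mottle, CT streaks), bit depths above 8, or pathology — so
passing tests say the pipeline behaves correctly on images with this
statistical structure, not that clinical image quality is guaranteed.
Measured at 256×256 and noise 0, ≥60% of 8×8 blocks have variance < 25
greylevels² and the 1-level detail subbands carry well under 15% of the
energy, in all four archetypes.

## Numerical choices

* All metric and pipeline arithmetic in float64; pixels cast from uint8.
* PSNR = 10·log10(255²/MSE); PSNR and SNR return `inf` (serialized as
  the string `"inf"`) on zero error instead of raising.
* SSIM uses global whole-image statistics with c1 = (0.01·255)²,
  c2 = (0.03·255)² and population (divide-by-n) variance/covariance; an
  optional sliding-window mode (dense 8×8 windows, mean of local SSIM) is
  available for comparability with common practice. NMSE is defined as
  MSE / mean(Y²).
* VQ ties break to the lowest index; reconstruction rounds half-up;
  index packing is MSB-first with zero padding per plane.
* Stagnation is measured as the range of the best-fitness history over
  the window; an alternative successive-delta mode is selectable.

## Known limitations

* **Rate-quality at desk scale.** On the 8-phantom 64×64 evaluation
  suite with H=16, K=64 the codec reaches round-trip PSNR ≈ 18–21.5 dB at
  CR ≈ 81% (header-dominated at this image size; the payload itself is
  384 bits against 32768). Two ceilings cap this: (i) with K=64 the
  decoder can emit only 64 distinct block patterns, and the *optimal*
  64-pattern quantizer (k-means in block space) already bounds this suite
  at 25.6–30.5 dB; (ii) derivative-free training of the ~2400-parameter
  autoencoder plateaus roughly 2.5× above what gradient training of the
  same architecture reaches, which is itself far from the linear-PCA
  bound because the output sigmoid must span the full normalized range.
  Larger images amortize the header and raise CR quality substantially;
  larger K and H raise fidelity at proportional rate cost.
* No entropy coding of indices; no rate-control loop — the operating
  point is set by (level, H, K).
* The recurrent context is trainable but not advantageous under small
  derivative-free budgets; it mainly exists to expose the
  sequence-context variant of the architecture.
* Greyscale 8-bit only; DICOM users should export to PNG/PGM first.
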