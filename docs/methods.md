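# Methods

## Problem setting

Block-face whole-brain fluorescence microscopy (e.g. fMOST) produces 16-bit
stacks whose sectioning leaves a characteristic set of degradations: an
asymmetric *flare* in which bright structures leak intensity into subsequent
sections along the sectioning (Z) axis; additive low-frequency backgrounds
that are separable along the image axes (mosaic seams, stripes, uneven
illumination); and pervasive sensor noise. `niend` removes each class with a
filter matched to its structure, then compresses the dynamic range into
8 bits without losing faint neurites, and finally cleans residual
high-frequency noise. All volumes are indexed `(z, y, x)`; SWC morphologies
are in voxel units of their stack.

## Diffusion filter

The flare is modeled as thermal diffusion of the restored signal of earlier
sections: the contamination of slice *n* by slice *i* is the restored slice
*i* convolved with a Gaussian whose width grows with the axial distance
*n − i*. Because Gaussian kernels compose, the total noise estimate obeys a
constant-memory recursion,

```
noise_1 = 0
noise_n = G_s ⊛ (res_{n−1} + noise_{n−1})
α_n     = k · mean(raw_n) / mean(noise_n)        (α_n = 0 if mean(noise_n) = 0)
res_n   = max(raw_n − α_n · noise_n, 0)
```

where `G_s` is a 2D Gaussian of std `s` pixels (reflect padding, kernel
truncated at 4σ so slice means entering `α_n` are unbiased). Expanding the
recursion shows each contribution is blurred once per slice of distance,
i.e. with an effective std `s·√(n−i)`; a literal linear-σ explicit sum
(`s·(n−i)` per contribution) is available as `sigma_mode="linear"` for
comparison, at O(Nz²) cost. The recursion is the default because it is what
makes the single-kernel composition valid, and it is what the forward flare
simulator implements — the two share one blur primitive, and an independent
explicit-sum implementation in the test suite pins the recursion down.

Parameters: `speed_s` (px/slice) defaults to `0.25 / lateral_res_um` — one
pixel of diffusion per 1-μm section at 0.25 μm/px, scaling inversely with
lateral resolution; `k ∈ [0, 1]` (default 0.9) tempers the subtraction.
With `k = 1` the filter inverts the forward model almost exactly: `α_n = 1`
would be the exact inverse, and `α_n = mean(raw_n)/mean(noise_n)` exceeds 1
by `mean(clean_n)/mean(noise_n)`, which is small on sparse content and whose
background effect is removed entirely by the clip at zero. On the default
phantom the round trip leaves an RMSE of ≈1.4% of the foreground intensity.
The default `k = 0.9` deliberately under-subtracts to protect faint
neurites from breakups. Traversal is in increasing Z (the flare direction);
`z_reverse` flips it for stacks stored with the opposite sectioning sign.
Recursion state is held in float64 slice buffers; the output volume is
float32, so memory stays near one float copy of the stack plus two slices.

## Orthogonal filter

With profiles `P_yz(z, y) = mean_x vol`, `P_xz(z, x) = mean_y vol` and
per-slice mean `m(z)`, the filter returns `vol − P_yz − P_xz + m`. The
direct sum of the two profiles counts each slice's mean twice, so it is
restored once; this makes any field of the form `f(y, z) + g(x, z)` vanish
identically (residuals at the 1e−15 level in float64), and the operator
idempotent pre-clip. The residual is clipped at zero by default.

## Instance-aware intensity shifting

The window `[lower, upper]` for the 8-bit conversion is chosen per image:
`lower` is the quantile keeping the brightest `keep_fraction` of voxels
(default 1%, adjustable ±0.5% for other resolutions) — neurites are sparse,
so this clears most of the background; `upper` is the lesser of
`lower + 255` and half the peak intensity of the soma region (a
soma-centered block, default 128 × 128 × 32 voxels in XYZ, clipped to the
volume), so very weak neurons are stretched across the full 8-bit range.
If the soma rule collapses onto the lower bound, the fixed span is used and
flagged. Rescaling is `round(255·clamp((v − lower)/(upper − lower), 0, 1))`
with round-half-away-from-zero fixed across platforms. The quantile and the
soma peak are taken on the high-pass output (the stage order is fixed).

## Wavelet denoising

Per XY-slice: 2-level Haar decomposition (level capped by slice size),
hard thresholding of every detail sub-band with the BayesShrink rule
`T = σ_noise² / σ_signal`, `σ_signal = sqrt(max(var(band) − σ_noise², 0))`,
where `σ_noise = median(|HH₁|)/0.6745` is estimated once per slice from the
finest diagonal band and reused at both levels; a band with no excess
variance is zeroed entirely. Approximation coefficients are untouched;
reconstruction is clamped to [0, 255] and re-quantized. Note a structural
degeneracy: when the intensity shift has cleared ≥ 99% of voxels, the
median |HH₁| is exactly 0, the thresholds vanish and the stage is a no-op —
consistent with the observation that its ablation has little effect on
sparse blocks; it acts where background survives (e.g. larger keep
fractions, dense regions).

## Quality metrics

The foreground mask rasterizes the radius-profiled gold morphology as node
spheres plus conical frusta along edges (point-to-segment distance against
the linearly interpolated radius; zero radii promoted to 0.5 voxel). The
background is the same construction with radii scaled 2-fold, minus the
foreground — a shell hugging the neuron. Metrics: SBC
`median(fg)/(median(bg)+1)`; background uniformity `Σ pᵢ²` of the
count-normalized histogram (256 equal-width bins over the observed range,
matching 8-bit granularity) of background z-scores after z-normalizing the
whole image with population std; foreground RSD `std(fg)/(median(fg)+1)`
(population std, for bit-stable tests). A constant background scores
uniformity 1 (the one-bin limit).

## Reconstruction scoring

Both morphologies are resampled to ≤ 1-voxel arc-length segments whose
midpoints carry the segment length as weight (total weight = cable length,
so the score is node-density invariant; discretization error ≤ step/2).
PDS is the weight fraction of samples farther than `thr` voxels (default
15, ≈ 3 μm; Euclidean in voxel units, anisotropy ignored by design) from
the nearest reference sample — exact nearest neighbors via a KD-tree,
verified against an all-pairs oracle. `precision = 1 − PDS(recon, gold)`,
`recall = 1 − PDS(gold, recon)`, F1 the harmonic mean with 0/0 → 0; an
empty reconstruction scores (0, 0, 0) with a warning. Morphologies without
edges fall back to unit-weight node points so ratios stay defined.

## Synthetic phantoms

`make_phantom` draws persistent random-walk neurites (unit steps, mild
direction jitter, reduced axial wander, reflecting margins) from a central
soma, with radii tapering 2.5 → 1 px and tube intensity `fg_intensity` with
Gaussian radial falloff (σ = r/2), max-combined; the gold SWC records every
other step. Defaults are one fixed set of study conditions: a
(64, 256, 256) block, 5 neurites of 300 steps (< 1% cable volume — the
sparsity the method targets), foreground 2000 counts, baseline 300, sensor
σ 30, separable fields of amplitude 300 with one step edge per axis
(mosaic seams), flare speed 1 px/slice, quantized to 16 bits last. All
generators are bitwise-deterministic under their seed. What the phantoms do
*not* model: real PSF optics, photon-statistics (Poisson) noise, neurite
curvature statistics, autofluorescent clutter; passing tests therefore
demonstrate correctness of the algorithms and the direction of the quality
gains, not field performance on real acquisitions.

`perturb_morphology` displaces a contiguous, exact arc-length fraction of a
gold morphology rigidly by a given distance (splitting the boundary edge at
the exact quota and detaching the moved piece, conserving cable length),
which yields fixtures with known expected deviation fractions. Near each
cut, gold cable within the distance limit of the kept structure still
counts as recalled, so expected recall is `1 − fraction` plus a band of
about `thr/L` per cut; fixtures use a long straight polyline (which never
approaches itself) so that band stays below 1%.

## Numerical and design choices

- Quantile via `numpy.quantile` (linear interpolation), over all voxels
  including zeros.
- Diffusion state float64 per slice, float32 output volume; orthogonal
  filter in float64 (its exactness guarantee is meaningful only there).
- LZMA compression rate = LZMA(preset 6) bytes / uncompressed TIFF bytes.
- `compute_bounds` soma center defaults to the volume center (blocks are
  soma-centered); override per image when they are not.
- Degenerate inputs: single-slice stacks pass the diffusion filter
  unchanged; slices smaller than 2×2 bypass the wavelet with a warning;
  constant images are rejected by the uniformity metric (zero variance).

## Known limitations

- The diffusion model assumes the flare grows monotonically with axial
  distance and is laterally isotropic; tilted or anisotropic flares are only
  partially removed.
- The instance-aware upper bound assumes one soma near the block center;
  multi-soma fields of view need an explicit `soma_center`.
- The wavelet stage can slightly distort neurite surfaces, to which some
  tracers are sensitive; it is trivially disabled (`wavelet_enabled: false`).
- Scores and quality metrics treat voxels isotropically; strongly
  anisotropic stacks may warrant rescaling before evaluation.
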