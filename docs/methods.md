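# Methods

This note documents the models and numerical choices behind `ciea`:
the curvelet transform, the two enhancement operators, the attention
classifier, the synthetic data, and the limits of what the test suite
demonstrates.

## Curvelet transform (`ciea.fdct`)

The transform tiles the 2-D frequency plane with smooth real windows:
an isotropic Meyer-type low-pass window (the coarse band) and, at each
finer scale, a ring of angular wedges.  Radial windows are built from
the C³ polynomial smooth step `ν(t) = t⁴(35 − 84t + 70t² − 20t³)`
applied to the log-radius, with octave boundaries at
`ρ_j = 2^(j−J) · ½` (cycles/sample); angular windows use the same ramp
on the wedge-normalised angle.  Because `ν(t) + ν(1−t) = 1`, adjacent
cos/sin windows satisfy `cos² + sin² = 1` exactly, and a final
pointwise normalisation by `√(Σ windows²)` makes the system an exact
tight frame.  Consequences, all asserted by tests:

* perfect reconstruction at machine precision (≪ 1e−6 relative L2),
* exact energy preservation (Parseval),
* linearity of both directions.

**Real coefficients.** For a real image, antipodal wedges carry
conjugate information; each wedge window is combined with its point
reflection (the window is π-periodic in angle and symmetrised exactly
under frequency negation on the FFT grid, including the Nyquist
row/column of even grids), so every coefficient matrix is real.
Orientations therefore live on the half-circle: `n_angles_coarse = 16`
full-circle directions become 8 stored wedge matrices.

**Wrapping.** Every band except the finest is wrapped onto a small
centred odd-sized frequency grid laid out in FFT order.  One grid is
used per scale (sized to the scale's annulus) rather than one per
wedge; since each band's support fits inside its grid, the wrapping is
a pure re-indexing and the transform stays exactly invertible, at the
price of some redundancy relative to parabolic per-wedge rectangles.
This trade — exactness and simplicity over minimal coefficient count —
is deliberate: the enhancement operators only need per-wedge matrices,
not critical sampling.

**Defaults.** `n_scales = max(2, ceil(log2 min(H,W)) − 3)` (3 at 64²,
5 at 224²), `n_angles_coarse = 16`, direction count doubling every
other scale toward fine — standard FDCT conventions.  Odd image sizes
are symmetrically padded to even and cropped back after inversion.
Images must be at least 32 pixels on a side.

## Contrast boost (`ciea.enhance`)

`fit_contrast_transform` bins the min-max-normalised coarse band into
`n = 1/step` intervals (default `step = 0.1`); bin `i` covers
`[(i−1)·step, i·step)`, the last bin closed so the maximum falls in bin
`n`.  `apply_contrast_transform` maps a normalised value `a` in bin `i`
to `b = P_{i−1} + p_i (a − (i−1)·step)/step` — the piecewise-linear
empirical CDF — then anti-normalises onto the source range.  Properties
(tested, including against a brute-force oracle and with hypothesis):

* nondecreasing; source min and max are fixed points;
* output confined to `[source_min, source_max]`;
* bin-histogram entropy non-decreasing (the distribution moves toward
  uniform);
* a constant matrix yields a flagged identity transform.

Note that "more uniform" does not always mean "higher variance": a
bimodal coarse band (dark background vs bright lung fields) can *lose*
RMS contrast while flattening, whereas the method's intended inputs —
low-contrast images with a concentrated histogram — gain it.  The test
suite checks the RMS claim on a peaked-histogram image and the entropy
claim unconditionally.

## Edge-coefficient enhancement

For each directional wedge the statistic `S_{j,d} = Σ|c_{j,d}|` is
computed; a wedge is edge-carrying when `S_{j,d}` exceeds a threshold.
The threshold is the mean of the `S` values *at the same scale* (scales
differ by orders of magnitude in total mass, so a global mean would
select entire scales); a global user-supplied τ can override it.
Within each selected wedge, coefficient magnitudes are amplified by
`u′ = M − (M − u)²/(M − m)` with `M, m` that wedge's own extreme
magnitudes, signs preserved.  Per-wedge extremes keep the gain
dimensionally consistent at the coefficient level; a wedge with
`M = m` is left unchanged, as are all non-selected wedges and the
coarse band.  The gain is monotone, never attenuates, and fixes both
extremes — all verified on dense grids.

`enhance_image` composes: forward transform → contrast boost on the
coarse band → wedge statistics → edge amplification → inverse
transform → clip to [0, 1].  It is deterministic.

## CBAM attention (`ciea.attention`, `ciea.network`)

Channel attention uses global average and max pooling per channel, a
shared two-layer bottleneck MLP (hidden width `C/r`, ReLU between the
layers, bias only on the output) and a sigmoid; spatial attention
stacks the channel-wise mean and max maps, convolves with one odd
`k × k` kernel (same-padding) and applies a sigmoid.  Defaults
`r = 16`, `k = 7` are the canonical CBAM values; the concatenation
order is [average; max].  The block multiplies channel weights then
spatial weights into the feature map, so it is an elementwise
contraction (`|F″| ≤ |F|`).  `ciea.attention` is the pure-forward
reference; `ciea.network.CBAMBlock` is the batched, differentiable
version, and the two are held to agree.

## Classifier and training (`ciea.network`)

Five blocks of conv(3×3, same) → BN → LeakyReLU(0.01) → CBAM →
max-pool(2×2), dropout (p = 0.3) after blocks 2, 4 and 5, then flatten
→ FC(64) → LeakyReLU → FC(1) → sigmoid.  CBAM sits after the
activation and before pooling in every block.  Pooling is plain block
maxima (unit post-pool scale, zero bias).  Default channel widths
(16, 32, 64, 128, 128) and the FC width were chosen to keep desk-scale
training fast; all are configurable.  The documented training defaults
are batch size 16, initial learning rate 1e−4, decay rate 0.96 per
epoch (continuous exponent, not staircase), Adam with β₁ = 0.9,
β₂ = 0.999, ε = 1e−8.

The whole stack — including backpropagation through batch norm, the
CBAM pooling argmaxes and the max-pool routing — is written directly
on numpy arrays.  Correctness is established three ways: closed-form
cases (identity kernels, constant inputs, the Adam first step),
brute-force loop oracles for conv/pool/attention, and end-to-end
numerical gradient checks on a float64 model.  Training runs in
float32 by default for speed; the numerical behaviour is otherwise
identical.

Evaluation mode (dropout off, BN running statistics) is deterministic;
training is deterministic given the seed and BLAS.

## Synthetic data (`ciea.synthetic`)

Images emulate the gross structure of a frontal chest radiograph
dataset: a dark background (0.12), two bright elliptical lung fields
(amplitude 0.38, fixed relative geometry, ±2 % per-image jitter),
and — for positives — 2–5 Gaussian opacities (peak 0.4, radius 3–8 px)
placed inside the lung fields, plus additive Gaussian noise
(σ = 0.03), clipped to [0, 1].  One RNG stream per dataset is consumed
in a documented order (label shuffle; per image: geometry, opacities,
noise), so generation is bit-reproducible.  With these defaults a
threshold on mean lung-field intensity alone separates the classes
with ≥ 90 % accuracy — the generator is *designed* to pose a learnable
problem.

What passing the learning test therefore shows: the implementation can
extract a real, localised intensity/texture signal end to end, and the
enhancement does not destroy it.  What it does not show: performance
on real radiographs, where anatomy, acquisition variation and label
noise dominate; no ribs, mediastinum or scatter are modelled, and the
absolute accuracies here are not comparable to clinical numbers.

## Pipeline and experiment scale (`ciea.pipeline`)

`run_pipeline` executes preprocess → (optional) enhancement of every
image → stratified 8:1:1 split → training → evaluation on all three
splits.  Enhancement precedes splitting and the split draws from its
own seed stream, so toggling enhancement can never change the
partition.  All randomness fans out of one master seed through named
sub-streams (synth, crop, split, init, train).

The desk-scale experiment used by the tests and by
`scripts/acceptance.py` is 400 images at 64×64 per seed, at most 20
epochs with early stopping once validation accuracy reaches 0.95,
three seeds, raw vs enhanced.  At the documented initial learning rate
some raw-input runs converge only partially within 20 epochs while the
enhanced runs converge reliably — the per-seed histories are in the
run outputs.  Larger inputs (224×224) and longer schedules are
supported but not exercised by default.

## Known limitations

* The FDCT is redundant (per-scale wrapping grids); memory grows with
  the direction count, which is irrelevant at these sizes but would
  matter at 4K resolution.
* The edge-selection threshold (per-scale mean) is a heuristic; τ is
  exposed for callers who want a calibrated value.
* Training is single-threaded numpy; it is a reference implementation,
  not a performance one.
* The synthetic generator's opacities are isotropic Gaussians; real
  infiltrates are textured and anisotropic.
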