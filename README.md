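# ciea

**Curvelet-domain image enhancement + attention-CNN classification for
chest-radiograph pneumonia screening.**

Chest X-rays are cheap and ubiquitous but notoriously low-contrast:
diagnostic detail (diffuse infiltrates, edges of opacities) sits on top
of a dominant low-frequency background. `ciea` implements a two-stage
recognition method for binary pneumonia screening:

1. **Curvelet-domain enhancement.** The image is decomposed with a
   tight-frame fast discrete curvelet transform (FDCT) into a coarse
   band and oriented wedge bands `c_{j,d}(k₁,k₂)`.  Two operations act
   on the decomposition:
   * *contrast boost* — the coarse band is min-max normalised, its
     values binned with width `step = 0.1`, and remapped through the
     piecewise-linear empirical CDF of the bin histogram (a
     histogram-equalisation variant whose extremes are fixed points);
   * *edge-coefficient enhancement* — wedges whose absolute-coefficient
     sum `S_{j,d} = Σ|c_{j,d}|` exceeds the per-scale mean are treated
     as edge-carrying, and each magnitude `u ∈ [m, M]` within them is
     amplified by the concave quadratic gain
     `u′ = M − (M − u)² / (M − m)`,
     which fixes the extremes and boosts mid-range edge responses.

   The enhanced image is recovered by the inverse transform.

2. **Attention CNN.** A five-block classifier — conv(3×3) → batch norm
   → LeakyReLU → CBAM → max-pool(2×2), dropout after blocks 2, 4 and 5,
   sigmoid output — trained with binary cross-entropy, Adam
   (β₁ = 0.9, β₂ = 0.999) and a continuous exponential learning-rate
   decay `lr(t) = lr₀ · 0.96^(t/decay_steps)`.  CBAM applies channel
   attention `M_c(F) = σ(MLP(AvgPool F) + MLP(MaxPool F))` followed by
   spatial attention `M_s(F) = σ(f⁷ˣ⁷[AvgPool_c F; MaxPool_c F])`,
   each multiplied into the feature map.

Everything — the FDCT, the enhancement operators, the CNN with
hand-written backpropagation, Adam — is implemented in numpy and
verified against brute-force loop oracles and numerical gradients.
Since clinical radiograph collections are rarely redistributable, the
package ships a seeded synthetic-data generator (lung-field ellipses,
diffuse Gaussian opacities for the positive class, additive noise) so
the entire pipeline runs and is tested without any download.

## Worked example

```python
import numpy as np
from ciea import (fit_contrast_transform, apply_contrast_transform,
                  SynthConfig, generate_dataset, fdct_forward,
                  wedge_statistics, enhance_image)

matrix = np.array([[ 11.3, 254.2,   1.0,   2.3],
                   [ 19.6, 200.1, 221.9, 230.6],
                   [  5.8,   9.7,   6.1, 210.9],
                   [219.3, 228.2,   8.8, 236.8]])
t = fit_contrast_transform(matrix, step=0.1)
print(t.frequencies)                       # bin occupancy of the matrix
print(apply_contrast_transform(matrix, t)[0])

img = generate_dataset(SynthConfig(image_size=64, n_images=4, seed=0))[0].pixels
coeffs = fdct_forward(img)
stats = wedge_statistics(coeffs)
print(coeffs.meta.n_scales, coeffs.meta.angles_per_scale, len(stats.selected))
```

prints

```
[0.5    0.     0.     0.     0.     0.     0.     0.0625 0.25   0.1875]
[ 52.5 254.2   1.    7.5]
3 (8, 8) 6
```

Half of the 16 coefficients fall in the lowest intensity bin, so the
CDF remap stretches the dark values apart (11.3 → 52.5) while the
matrix minimum (1.0) and maximum (254.2) map to themselves.  The 64×64
synthetic lung image decomposes into 3 scales with 8 orientation wedges
at each directional scale, 6 of which exceed the per-scale edge
threshold and get amplified.

Running the full pipeline on synthetic data (400 images, 64×64,
8:1:1 stratified split, at most 20 epochs with early stop at validation
accuracy 0.95):

```python
from ciea import PipelineConfig, TrainConfig, run_pipeline
m = run_pipeline(PipelineConfig(
    synth=SynthConfig(image_size=64, n_images=400), crop_size=64,
    enhancement=True,
    training=TrainConfig(epochs=20, target_accuracy=0.95), seed=1))
print(m.accuracy)   # {'train': 1.0, 'validation': 1.0, 'test': 1.0}
```

The synthetic classes are separable by construction, so a converged run
reaches ≥ 0.9 held-out accuracy; see `docs/methods.md` for what this
does and does not say about real radiographs.

## Command line

```bash
ciea synth   --out data --n-images 100 --image-size 64 --seed 0
ciea enhance --in data --out enhanced --step 0.1 [--scales J] [--angles A] [--tau X]
ciea run     --out results --n-images 400 --crop-size 64 --epochs 20 \
             --batch-size 16 --lr 1e-4 --decay-rate 0.96 --dropout 0.3 --seed 1
ciea evaluate --checkpoint results/checkpoint.npz --config results/config.json --in data
```

`ciea run` writes `metrics.txt`, `history.csv`, `checkpoint.npz` and a
`config.json` snapshot to the output directory.

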