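# hicres

Resolution enhancement of Hi-C contact matrices with a residual
convolutional network, plus everything needed to exercise it end to end:
coverage-thinning simulation, synthetic chromosome generation, patch
extraction/stitching, and a reproducibility metric suite.

## The problem

A Hi-C contact matrix M records, for one chromosome cut into fixed-width
bins (10 kb here), the number of read pairs M[i, j] linking bins i and j.
Fine chromatin structure — loops, sharp domain boundaries — only becomes
visible at high sequencing depth, and depth requirements grow quadratically
with resolution. Enhancement methods instead *predict* the high-coverage
matrix from a cheap low-coverage one, treating the contact map as a
single-channel image and learning the mapping from paired (thinned,
deep) experiments.

The model here is a moderate-depth residual CNN: two size-preserving
feature convolutions (7×7, 5×5; 32 maps), a residual bottleneck block
(1×1→128 + ReLU, 1×1→32, 7×7→32, additive skip), four unpadded "crop"
convolutions (kernels 5, 3, 5, 3) that shrink a 40×40 input window to the
28×28 output it predicts, a second residual block, and a 7×7 + linear 5×5
prediction head. Training minimizes

    L(Θ) = (1/n) Σᵢ ‖F(Xᵢ) − X̃ᵢ‖²

over paired low/high patches (Xᵢ, X̃ᵢ) with Adam, Glorot initialization and
early stopping on validation MSE. Low-coverage inputs are simulated from
deep data by binomial read thinning at ratios such as 1/16 and 1/25.
Enhancement quality is scored against the deep matrix by per-distance
Pearson correlation, the stratum-adjusted correlation coefficient (SCC,
HiCRep-style), SSIM, aggregate peak analysis (P2LL) and interaction-overlap
ratios. See `docs/methods.md` for the full model description and design
rationale.

The network and its training loop are implemented directly in numpy
(convolutions as shifted GEMMs with hand-derived gradients), so the package
runs on a plain scientific-Python stack with no deep-learning framework.

## Worked example

```python
import numpy as np
from hicres import (
    ContactMatrix, HiCEnhancer, TrainConfig, default_spec, make_pair,
    plan_patches, extract_inputs, extract_targets, compare, EvalSettings,
)
from hicres.pipeline import enhance_matrix

# Two synthetic 500-bin chromosomes (5 Mb at 10 kb): train and held-out.
ratio = 1 / 16
high_tr, low_tr = make_pair(default_spec(seed=111, n_bins=500), ratio)
high_ev, low_ev = make_pair(default_spec(seed=121, n_bins=500), ratio)

# Overlapping 40x40 inputs from the thinned matrix, tiling 28x28 targets
# from the deep matrix, keeping windows within 2 Mb of the diagonal.
plan = plan_patches(500, max_distance=2_000_000)
x = extract_inputs(low_tr, plan)
y = extract_targets(high_tr, plan)

model = HiCEnhancer(x, y)
res = model.fit(TrainConfig(batch_size=8, max_epochs=120, patience=15,
                            input_rescale=1 / ratio, seed=141))
print(res.summary())

# Enhance the held-out chromosome and score it against its deep matrix.
enhanced = enhance_matrix(res, low_ev, ratio, max_distance=2_000_000)
baseline = ContactMatrix(low_ev.counts / ratio)
for name, cand in [("baseline", baseline), ("enhanced", enhanced)]:
    rep = compare(high_ev, cand, EvalSettings(max_distance=2_000_000))
    pearson = rep.pearson_by_distance
    print(f"{name}: SSIM {rep.ssim:.3f}  SCC {rep.scc:.3f}  "
          f"Pearson(<200 kb) {np.nanmean(pearson[:20]):.3f}  "
          f"mean Pearson(<2 Mb) {rep.mean_pearson:.3f}")
```

Output of the equivalent packaged run (`hicres run --seed 1`, ~15 minutes
on one CPU core; the simulation seeds there are derived from the run seed):

```
Hi-C enhancement network — fit summary
==============================================
parameters                  265121
input -> output size        40 -> 28
epochs run                  120
best epoch                  114
best validation MSE         0.000854682
batch size                  8
learning rate               0.001
input rescale               16.0
value scale                 0.00923446
seed                        141

baseline: SSIM 0.901  SCC 0.975  Pearson(<200 kb) 0.452  mean Pearson(<2 Mb) 0.284
enhanced: SSIM 0.954  SCC 0.989  Pearson(<200 kb) 0.713  mean Pearson(<2 Mb) 0.208
```

The baseline is the thinned matrix rescaled by 1/ratio — an unbiased but
noisy estimate of the deep matrix. The trained network clearly beats it
where there is structure to recover: SSIM, SCC, and per-distance Pearson
up to a few hundred kb all improve (at 0–50 kb the correlation rises from
0.59 to 0.87 here). Beyond ~0.5 Mb the synthetic intensity field is almost
featureless between loop anchors, and there the baseline retains an edge
the network cannot beat at desk scale — it shares its surviving reads with
the reference matrix, which alone is worth a correlation of √(1/16) = 0.25
per stratum. That pulls the *distance-averaged* Pearson of the enhanced map
below the baseline's even while every structured distance band improves;
`docs/methods.md` discusses this trade-off and what it does and does not
say about real data.

The same workflow is available from the shell:

```sh
hicres simulate --n-bins 500 --seed 11 --out-prefix sim
hicres downsample sim_high.txt sim_low16.txt --ratio 0.0625 --seed 1
hicres run --seed 1 --run-dir runs/demo      # full pipeline, packaged demo
hicres evaluate sim_high.txt runs/demo/enhanced.txt
```

`hicres run` writes every stage artifact plus a manifest with per-stage
checksums into the run directory and can resume from any completed stage.

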