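# Methods

## Problem and scope

A Hi-C experiment yields, per chromosome, a symmetric contact matrix whose
entry (i, j) counts read pairs linking genomic bins i and j at a fixed bin
width (here 10 kb). Sequencing depth sets the usable resolution: a matrix
built from few reads is sparse and noisy, and fine structures (chromatin
loops, sharp domain boundaries) drown in Poisson noise. This package
implements a residual convolutional network that maps low-coverage contact
matrices to estimates of their high-coverage counterparts, together with the
machinery needed to train and judge it: coverage thinning to simulate
low-depth data, patch extraction/stitching, a synthetic contact-map
generator, and a metric suite (distance-stratified Pearson, SCC, SSIM,
APA/P2LL, interaction-overlap ratios).

## Data model and thinning

Matrices are dense symmetric arrays wrapped in `ContactMatrix`; sparse
`start1 start2 count` triplet text (0-based bp bin starts) is the on-disk
format. No balancing/normalization (KR or ICE) is applied anywhere: the
network is trained on raw counts.

Low-coverage data is simulated by per-entry binomial thinning: an entry with
count k becomes Binomial(k, ratio), mirrored across the diagonal. Retaining
each read pair independently with probability `ratio` before matrix building
produces exactly this distribution at the matrix level, so the toolkit never
needs read-level files. Thinning a matrix of N total reads leaves ratio × N
reads in expectation; e.g. 2.521 billion reads thin to 0.158 billion at
1/16 and 0.101 billion at 1/25. Diagonal entries are thinned like any other
entry. Hypergeometric (without-replacement) thinning differs negligibly at
these depths and is not implemented.

## Patch geometry

Full matrices are cut into 40×40 input windows whose anchors advance in
steps of 28 bins along both axes, so adjacent windows overlap by 12 bins.
The training target for a window is the 28×28 block offset 6 bins into it;
target blocks therefore tile the matrix without overlap. In 1-based prose
coordinates: input rows [1, 40] map to target rows [7, 34], input rows
[29, 68] to [35, 62]. Predicted targets are stitched back at their anchors;
cells no target covers (the 6-bin borders, the remainder past the last full
window, and any windows excluded by an optional 2 Mb center-distance cap)
are filled from the 1/ratio-rescaled low matrix, and the result is
symmetrized by transpose-averaging. A helper also provides the fixed
five-group split of the 22 autosomes ({1–4}, {5–8}, {9–12}, {13–17},
{18–22}) used for chromosome-level cross-validation on real data.

## Network

The network maps (n, 40, 40, 1) stacks to (n, 28, 28, 1):

1. feature extraction: 7×7 and 5×5 convolutions, 32 maps, size-preserving;
2. residual bottleneck block: 1×1 → 128 maps + ReLU, 1×1 → 32 maps,
   7×7 → 32 maps size-preserving, additive skip from the block input, no
   activation after the addition;
3. cropping: four unpadded convolutions with kernels 5, 3, 5, 3 (32 maps,
   ReLU each), shrinking each side by 4+2+4+2 = 12 bins;
4. a second identical residual block;
5. prediction: 7×7 (32 maps, ReLU) and a linear 5×5 convolution to 1 map.

Padding is not a free choice: reaching 28 from 40 with those crop kernels
forces size-preserving padding everywhere except the four crop layers. ReLU
placement inside the residual block (after the first 1×1 only) and after
each crop layer follows the published description; ReLUs after the two
feature-extraction layers and the first prediction layer are this package's
interpretation of standard practice, with the final 5×5 layer linear.

The loss is the mean squared error between predicted and true high-coverage
patches. It is implemented as a per-element mean; the per-patch
squared-norm convention differs only by the constant factor 784 (= 28²) and
has the same optimum.

Because no deep-learning framework is part of the supported dependency set,
the network is implemented directly in numpy: convolutions as sums of
shifted GEMMs (one (n·oh·ow, c_in) × (c_in, c_out) product per kernel
offset, which profiled ~2× faster than transposed im2col on one CPU core),
hand-derived backward passes, Glorot-uniform initialization with zero
biases, and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, step size 1e-3). A
finite-difference gradient check is part of the test suite; note that
zero-initialized biases put dead pixels exactly on the ReLU kink, where
one-sided finite differences legitimately disagree, so the check nudges
biases off zero first.

### Training stabilizers and value scaling

Two numerical safeguards proved necessary on CPU-scale runs and are on by
default:

* **global gradient-norm clipping** (default 5.0 in normalized units). A
  single extreme batch can otherwise blow the ReLU network into a dead,
  constant-output state from which it does not recover (observed as a
  sudden 50× jump in training loss that persisted for the rest of the run).
* **plateau learning-rate halving** (patience 8 epochs, floor 1e-4 — the
  floor matters because small validation sets are noisy enough to trigger
  spurious halvings), with early stopping on validation MSE (patience 10
  by default) and best-weight restoration.

Raw counts span orders of magnitude and the thinned input sits a factor
1/ratio below its target, which makes first-order optimization crawl within
a small epoch budget. `fit` therefore multiplies inputs by `input_rescale`
(normally 1/ratio, putting input and target on a common coverage scale) and
divides both by a value scale derived from the 99th percentile of the
training targets. This is an affine reparameterization — the optimum is the
identical network up to a first/last-layer rescaling — and the constants are
stored in the checkpoint and inverted at prediction time, so the public
surface still consumes and produces raw counts. An optional `clip` cap on
input counts exists and is off by default.

## Synthetic contact maps

The generator emulates the marginal statistics that matter for this task:

* power-law distance decay, λ = A·(d+1)^(−α) with α = 1;
* TADs: the gaps between consecutive boundary indices form domains whose
  internal intensities are multiplied by `tad_boost` (default 2);
* loops: 3×3 neighborhoods around anchor pairs multiplied by their strength
  (one-bin anchor uncertainty is typical at 10 kb);
* Poisson counts drawn per upper-triangle entry and mirrored.

Defaults describe a desk-scale chromosome: 500 bins (5 Mb at 10 kb),
amplitude A = 150, boundaries every 60–90 bins, a handful of loops of
strength 4. A = 150 was chosen so that the 1/16-thinned matrix lands in the
sparse regime that motivates enhancement in real data (most off-diagonal
entries 0 or 1) while the high matrix remains informative; it corresponds
to a few-fold lower depth than a real combined high-coverage experiment,
which keeps CPU training times in minutes.

What the generator does **not** emulate: A/B-compartment checkerboards,
fine-scale intensity heterogeneity beyond TADs/loops, mappability and
fragment-length biases, or inter-chromosomal contacts. Per off-diagonal
stratum the only intensity variation is TAD membership and the rare loop
pixels, which is *less* within-stratum structure than real chromatin has.
This matters when reading the evaluation: a thinned matrix is a subsample
of the very reads in its high matrix, so the rescaled-thinned baseline gets
a per-stratum Pearson floor of √ratio (= 0.25 at 1/16) "for free", while a
model can only beat that by both denoising and passing surviving read
spikes through. Passing the end-to-end test here is therefore evidence the
training loop works, not a forecast of the scores reachable on real data.

## Evaluation metrics

* **Per-distance Pearson**: correlation of the paired d-th diagonals;
  constant diagonals yield an explicit NaN marker, never a silent drop.
* **SCC**: both matrices are mean-smoothed with a (2h+1)² moving average
  (h = 5 by default; edge windows average in-bounds cells only), then
  per-stratum correlations for d = 1 … 2 Mb are combined with weights
  N_d·s_d(A)·s_d(B). Zero-variance strata are skipped. The main diagonal is
  excluded from strata.
* **SSIM**: uniform 11×11 window over all fully contained positions, sample
  (ddof = 1) variances/covariance, stabilizers C1 = (0.01 L)², C2 =
  (0.03 L)² with L defaulting to the maximum value over both matrices
  (count matrices have no fixed dynamic range; configurable).
* **APA/P2LL**: windows of radius 10 around loop anchors (canonicalized to
  i < j) are averaged; P2LL is the center over the mean of the 3×3
  lower-left (short-distance) corner. Anchors whose window would cross an
  edge or the main diagonal are dropped with a warning.
* **Interaction overlap**: fraction of reference calls within a distance
  range (50–250 kb, 250 kb–1 Mb, 1–2 Mb by default; lo ≤ dist < hi)
  recovered by a test call set, after canonical pair ordering. Significance
  calling itself (Fit-Hi-C-style) and TAD calling are out of scope; only
  the overlap arithmetic applied to external call lists is provided.

Every metric is cross-checked in the tests against an independent explicit
double-loop implementation on small random fixtures (1e-10 tolerance;
1e-6 for SSIM).

## The desk-scale end-to-end experiment

The packaged demo (also what `scripts/acceptance.py` reruns) simulates two
independent 500-bin chromosomes, thins both at 1/16, trains on patches of
the training chromosome (windows capped at 2 Mb center distance), and
enhances the held-out chromosome. The trained model is compared against the
16×-rescaled thinned baseline on SSIM, per-distance Pearson (≤ 2 Mb) and
SCC, all measured against the held-out high-coverage matrix. Problem sizes
(500 bins, 120 training patches, batch 8, ≤ 120 epochs with early
stopping) keep the experiment near 15 minutes on one CPU core; the
five-group chromosome scheme is provided for real-data runs but the demo
uses single synthetic chromosomes.

Representative seed-1 results: SSIM 0.954 vs 0.901 for the baseline; SCC
0.989 vs 0.975; per-distance Pearson 0.87 vs 0.59 below 50 kb and 0.66 vs
0.41 at 50–200 kb. Two caveats deserve emphasis, both consequences of the
synthetic generator rather than of the method:

* **The baseline's SCC is already 0.975.** After 11×11 mean smoothing the
  rescaled thinned matrix is an excellent estimate of a generator whose
  per-stratum structure is piecewise constant, so the SCC headroom above
  the baseline is tiny. An oracle evaluation with the true intensity field
  — the best any method could do — reaches SCC 0.998, i.e. a ceiling gain
  of only ~0.02. The trained network recovers about 60% of that ceiling.
* **The distance-averaged Pearson favors the baseline.** The thinned
  matrix is a subsample of the very reads in the reference matrix, so at
  *every* distance its per-stratum correlation has a floor of √ratio
  (= 0.25 at 1/16) even where the intensity field is featureless. Between
  0.5 and 2 Mb the generator has essentially no within-stratum intensity
  variation outside loop anchors, so matching that floor requires
  reproducing the exact positions of individual surviving reads. The Bayes
  predictor x + (1−ratio)·λ does this and attains mean Pearson 0.41 (vs
  baseline 0.28); gradient training approaches it far too slowly on one
  CPU (a 220-epoch run plateaus near 0.21), while every distance band
  below ~0.5 Mb — where real biological structure lives — improves
  markedly. On real Hi-C data the per-stratum structure is rich at all
  distances, which is why published comparisons show enhanced matrices
  beating the thinned baseline across the full range; the synthetic
  generator under-represents exactly that richness.

## Known limitations

* Dense matrices only; a full human chromosome 1 at 10 kb (~25k bins) fits
  in memory but SSIM's windowed implementation materializes sliding-window
  views and is best kept to ≤ ~3000 bins per call.
* The published training regime (millions of patches, GPU batches of 256)
  is out of desk-scale reach; the defaults here are honest scaled-down
  stand-ins, not a reproduction of published scores.
* The SCC weighting follows the variance-weighted HiCRep form; rank-based
  variants exist and will differ in the third decimal on typical inputs.
* Checkpoints store raw parameter arrays with a JSON header; they are not
  portable to other toolkits.
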