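# Methods

This note documents the model, the loss, the synthetic data the package is
exercised on, and the numerical and design choices a maintainer would want
spelled out. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Above-ground biomass (AGB) estimation from nadir RGB plot images is a deep
*regression* problem: a continuous, strictly positive mass (grams per plot or
g/m²) must be predicted from a canopy photograph dominated by occluded green
matter over soil. Field label distributions are continuous and imbalanced —
most plots carry mid-range mass, the tails are sparse — which is exactly the
regime where a plain L1-type loss under-uses the relational structure between
samples. The package couples

1. **SCDR**, a supervised contrastive loss for regression, and
2. **BioUMixer**, a hierarchical residual fusion backbone,

and trains them end to end.

## The SCDR objective

Each training image is augmented into two views (crop, horizontal/vertical
flip, colour-contrast jitter, per-channel standardization); both views keep
the source label. Inside one augmented batch of 2N views, pair (i, j) is

* **positive** when |y_i − y_j| ≤ ω,
* **negative** when |y_i − y_j| > ω and |ŷ_i − ŷ_j| ≤ ω
  (the model currently *confuses* the two),
* **unpaired** otherwise; unpaired views do not enter the loss at all.

A view with at least one negative is an **anchor**; non-anchors contribute
exactly zero. With L2-normalized embeddings v and temperature τ the
per-anchor loss is the single-log form

    L_j = −log [ (1/N⁺_j) Σ_{i∈P⁺} e^{v_j·v_i/τ}
                / ( Σ_{p∈P⁺} e^{v_j·v_p/τ} + Σ_{q∈P⁻} S_{j,q} e^{v_j·v_q/τ} ) ]

averaged over all 2N views, and the total objective is
`L_sum = α·L_reg + β·L_SCDR`. The per-negative *thrust*

    S_{j,q} = min( η / (Sim_l(y_j,y_q) · Sim_f(v_j,v_q)), S_max ),
    Sim_l = exp(−|Δy|/σ_l),   Sim_f = max((1+cosθ)/2, ε_f)

pushes harder on negatives whose labels are far apart, and damps the push
when the features already look alike — which is what limits the damage a
mislabelled pair can do. Pairing decisions and thrust weights are computed
from *detached* predictions and embeddings: gradients flow only through the
exp(v·v/τ) terms. With η = 0 the loss is provably independent of every
negative-pair embedding (the denominator loses its negative terms), a
property the suite checks bit-exactly.

### Loss hyperparameters

| name | default | units | role |
|------|---------|-------|------|
| τ    | 0.2     | —     | logit temperature; lower sharpens contrast |
| η    | 0.01    | —     | thrust scale for negative pairs |
| α    | 1       | —     | regression-loss weight |
| β    | 3       | —     | contrastive-loss weight |
| ω    | 0.1·std(y_train) | grams | label/prediction similarity threshold |
| σ_l  | 0.25·std(y_train) | grams | label-kernel scale inside the thrust |
| ε_f  | 0.05    | —     | feature-similarity floor |
| S_max| 100     | —     | thrust cap |

τ, η, α, β follow the grid optima of the method's ablations. ω and σ_l are
data-dependent by construction: fixing them as fractions of the
training-label standard deviation keeps the pairing rule scale-free across
crops whose masses differ by orders of magnitude; both are computed once at
run start and frozen. The same ω serves the label test and the prediction
test. S_max prevents blow-up as both similarities approach their floors.

Choices the loss definition left open, decided here: (1) the 1/N⁺ factor
sits *inside* the logarithm (the printed single-log form, not an average of
per-positive logs); (2) a view's own sibling is in P⁺ and the view itself is
excluded from all sums, so N⁺ ≥ 1 always holds; (3) unpaired views appear
nowhere in the denominator; (4) embeddings are normalized before every dot
product so e^{v·v/τ} is bounded and the temperature keeps one fixed meaning.

### Regression term

`L_reg` is the mean absolute error or its focal variant
`mean(sigmoid(γ|e|)^p · |e|)` with γ = p = 1 (default), which up-weights
large errors; the sigmoid weight is detached so the focal factor acts as a
weighting, not an extra gradient path. Labels are z-scored internally for
this term (predictions are mapped back to grams for metrics and for the
ω-pairing, which is defined in label units). With raw gram-scale targets in
the thousands, an L1 loss under Adam at lr 10⁻³ could not move the output
bias to the data range within any reasonable step budget; standardizing the
target is the standard remedy and is recorded in the checkpoint.

## BioUMixer

The backbone maps an image to a d_emb-dimensional embedding v (consumed by
the loss) and a scalar prediction ŷ = MLP(v):

    patch embed (p×p, non-overlapping)
    → stage s = 0…S−1:  FeatureBlock × b_s, BioBlock × b_s,
                        SimAM, 2×2 merge (except last stage)
    → mixer head (token MLP + channel MLP) → pooled embedding v → MLP → ŷ

* **FeatureBlock** (ConvNeXt lineage): depthwise 3×3 → BatchNorm → 1×1
  expansion (×4) → GELU → GRN → 1×1 reduction → DropPath → residual add.
* **GRN** divides each channel's spatial L2 norm by the cross-channel mean
  of those norms and rescales the input through a zero-initialized affine
  with residual — an exact identity at initialization, scale-invariant in
  its ratio up to the ε-guard.
* **BioBlock** (sandwich layout): pointwise FFN (ReLU, ×2) → depthwise 3×3
  token mixer gated by SimAM → pointwise FFN, each sub-layer residual.
* **SimAM** weights every position by `sigmoid((x−μ)²/(4(σ̂²+λ)) + 0.5)`
  with μ and the unbiased variance σ̂² taken over the channel's spatial
  positions (λ default 10⁻⁴). Constant channels shrink uniformly by
  sigmoid(0.5); λ→∞ reproduces that limit everywhere; 1×1 maps are rejected
  because the variance is undefined.
* **U-like hierarchical residual**: the i-th block of a given kind in stage
  s feeds the i-th block of the same kind in stage S−1−s (for s < S−1−s);
  the early map is average-pooled (or nearest-upsampled) to the late
  resolution, 1×1-projected when widths differ, and fused by addition.
  Addition rather than concatenation keeps the ablation cases
  parameter-comparable.

Depths, widths and head sizes are configuration, not architecture: the
**tiny** preset (64×64 input, patch 4, widths 32/64/128, one block of each
kind per stage, d_emb = 128, ≈0.5 M parameters) is what every test and the
acceptance script use; a **standard** preset (224×224, two blocks per
stage) is the default `ModelConfig`. The "attention" units between stages
are SimAM instances — parameter-free, so they never confound the ablation
parameter counts. GELU is used in the FeatureBlock/head (its sigmoid
approximation x·σ(1.702x), whose error is far below any tolerance used
here), ReLU in BioBlock FFNs. The exact sub-layer orders inside the two
blocks are canonical choices documented above; the prose they derive from
fixes only the ingredient list.

Three module families can be toggled off (replaced by the identity) to form
the five ablation cases: case1 = main module only, case2 = no long skips,
case3 = no FeatureBlocks, case4 = no BioBlocks, case5 = the full model.

## Numerical core

No deep-learning framework is assumed: the package carries a compact
reverse-mode autodiff engine over numpy arrays (`bioumixer.autodiff`) with
exactly the operator set the model needs. Convolutions are realised as
reshapes + matmuls (patch embedding, 1×1, 2×2 merges) and a fused
depthwise-3×3 primitive; every primitive's gradient is tested against
central finite differences. Model weights are float32; loss-level
mathematics run in the dtype of their inputs (the oracle tests use
float64). The contrastive softmax subtracts a per-row detached maximum over
the entries that actually appear in the ratio, so the single-log form is
evaluated stably at any τ.

Training uses Adam (β₁ = 0.9, β₂ = 0.999) with a per-step cosine-annealed
learning rate from 10⁻³ to 10⁻⁵ and batch size 16 (→ 32 views); 80 epochs
is the full-scale default, 10 epochs the desk-scale preset. Gradient
clipping is available but off by default: a global-norm clip interacts with
the α/β weighting of the two loss terms and would silently rescale the
regression gradient whenever the contrastive term dominates. Divergence is
guarded by a NaN check that aborts with the offending batch. A 20%
validation split drives best-MAE checkpoint selection. All randomness
(splits, init, augmentation order) derives from the single config seed, and
BatchNorm running statistics are the only train-time state carried into
evaluation, so two runs with one seed are bit-identical end to end.

## Synthetic scenes

The generator emulates the *statistical* structure of biomass plot imagery,
not its appearance: green foliage ellipses (3 per plant, 2–6 plants) and
red fruit ellipses over textured brown soil, with occlusion resolved by
paint order, at 64×64 px. The label is exactly

    biomass = 1.3 g/px · #foliage + 2.5 g/px · #fruit + N(0, 60 g),

floored at 1 g. Coverage is drawn from a right-skewed Beta(1.8, 3.5) mapped
to 5–65% of the frame, so labels span roughly 200–2500 g, continuous and
right-skewed — the imbalanced regime the loss targets, at the gram scale of
fruit-plus-stem field plots. With the noise off, the stored label equals
the recount from the rendered class map bit-exactly, which the suite
verifies.

What passing desk-scale tests do and do not show: the scenes provide a
learnable, monotone pixel→mass signal with label noise and occlusion, so
they exercise pairing, thrust, the backbone and the training loop under
realistic label statistics. They do not contain perspective, lighting or
phenological variation, so desk-scale metric values say nothing about
accuracy on real field imagery — only that the machinery optimizes what it
claims to optimize.

## Desk-scale experiment

The packaged experiment (also recomputed by `scripts/acceptance.py`) trains
the tiny preset on 200 train / 50 test scenes for 10 epochs, three seeds per
arm: the full objective (α = 1, β = 3, τ = 0.2, η = 0.01) against the pure
regression baseline (β = 0). Reported quantities: mean test MAE per arm,
mean Spearman correlation between predictions and labels, and the change,
from initialization to trained, in the Spearman correlation between
pairwise embedding distances and pairwise label distances on the test set.
The embedding-order statistic is computed on the unit sphere (embeddings
L2-normalized) because that is the feature space the contrastive loss
actually operates in. Problem sizes were chosen so the whole experiment
runs in minutes on one CPU core; they are the package's fixed study
conditions, not tunables.

At this scale a run is only ~100 optimizer steps, so three-seed means of
the MAE comparison and of the embedding-order gain carry visible run-to-run
variance: different seed sets can land on either side of a few-percent
margin. The packaged tests fix one seed set; the acceptance script derives
its seeds from `--seed` and reports whatever they produce.

## Known limitations

* CPU-only and deliberately small: the autodiff engine favours clarity and
  testability over throughput; full-scale (224², 80-epoch) training is
  supported but slow without acceleration.
* MAPE is undefined at zero labels; the report flags it rather than
  imputing.
* The thrust form, similarity kernels and the placement of 1/N⁺ are
  documented package choices among several defensible readings of the
  method; sensitivity to the alternatives is not explored here.
* Scene realism is minimal by design; no claim is made about transfer to
  real imagery without retraining.
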