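# Methods

This note documents the models, algorithms and numerical choices behind
`rnadotseg`, and what its synthetic-data experiments do and do not show.

## Problem setting

Chromogenic RNAscope produces one small brown (DAB) dot per detected RNA
transcript on haematoxylin-counterstained tissue. The goal is to recover the
set of dot coordinates from an RGB image patch. Ground truth comes as point
annotations, so the pipeline is: pixel segmentation → cluster splitting →
centroid extraction → point-set matching. Scoring uses one-to-one matching at
a 5-pixel Euclidean tolerance; F1 is the headline statistic. Weakly stained
slides put the positive class below 1% of pixels, which drives every design
choice below (recall-weighted loss, heavy regularization, cross-shaped
targets).

## Synthetic patch generator

Real annotated slides are typically not shareable, so the generator emulates
them with fully known ground truth. Colours are handled in BGR order
throughout.

**Dot masks.** A dot is a *subtractive* 3-channel mask: the centre pixel is
set to `255 − colour`, a circular Gaussian blur spreads it, and the mask is
rescaled per channel so the centre regains its pre-blur value; subtracting
the mask from the image then darkens a faded disc toward `colour` at the
centre. Primary dots interpolate linearly between light yellow
`(225, 253, 255)` and dark brown `(160, 200, 217)` with one shared
interpolant for all channels, and use a 9×9 kernel. The dark-centred
secondary variant uses fixed colour `(200, 210, 215)` (≥ 40 darkening per
channel) with a 5×5 kernel and is added onto a primary mask at a ±1-px random
offset. Per-dot perturbations, applied in order: each cardinal half-axis
stretched by 0–3 px, anisotropic scaling by `(sx + r', sy + r')` with
`sx, sy ~ U(0.25, 0.5)` and the shared offset `r' = 0.4 r²` (large dots rare),
multiplicative per-pixel noise in `[0.975, 1.025]`, and rotation by a random
integer degree.

**Per-patch structure.** Dot count `n = round(2^(1+5r))`, `r ~ U(0, 1)` — an
exponential scale from 2 to 64 reflecting that most patches have few dots and
some have many. Each patch draws its primary colours from one random window
covering 20% of the yellow→brown axis (dots within a patch resemble each
other); 25% of patches carry secondary dots, and within such a patch each dot
is secondary with probability `~ U(0, 0.5)`. Dots are placed uniformly with
rejection until every pair is ≥ 3 px apart (1000 attempts per dot, then a
`PlacementError`).

**Background.** The package pastes dots onto a generated background rather
than real tissue: a pale bluish-grey field (blue channel brightest, matching
haematoxylin) with smooth low-frequency variation and darker elliptical
nucleus-like regions, clipped so no pixel drops below 100 — dots always stay
distinguishable. This is the main divergence from real data: real tissue has
sharper texture, stain variability, and confusable structures. Passing the
end-to-end test therefore demonstrates that the machinery (generation,
training, calling, scoring) works and can recover dots, not that the network
would reach any particular accuracy on tissue.

**Determinism.** Every routine draws from an explicit
`numpy.random.Generator`; one seed reproduces a patch bit-exactly.

## Network

The encoder follows ConvNeXt: 4×4 stride-4 stem convolution + channel layer
norm, then four stages of residual blocks (7×7 depthwise convolution → layer
norm → 1×1 expansion ×4 → GELU → 1×1 reduction → layer scale → stochastic
depth), with 2×2 stride-2 downsampling between stages. Sizes: `base`
(depths 3/3/27/3, widths 128/256/512/1024), `small` (96/192/384/768), and a
reduced `tiny` preset (2/2/4/2, 32/64/128/256) for CPU-scale work — `tiny`
here is *not* the published ConvNeXt-tiny.

Because the stem already downsamples 4×, the nested (U-net++) decoder grid is
applied only between 1/4 and 1/32 resolution: nodes `X[i][j]` (level i,
column j ≥ 1, i+j ≤ 3; six nodes over four levels) receive all same-level
predecessors plus the 2×-upsampled lower node, concatenated, projected to the
level width by a 1×1 convolution, then passed through one custom upscale
block. The custom block replaces layer norm with batch norm, adds a second
batch norm on the skip path, applies DropOut (feature-wise) *before* the
branch point rather than DropPath on the residual branch, and appends a
closing activation after the residual sum — changes aimed at making shallow,
from-scratch upscaling layers trainable under heavy class imbalance.

A final section restores full resolution: twice [2×2 stride-2 transpose
convolution + 3 ConvNeXt blocks], then a 1×1 projection with sigmoid.
Regularization there is configurable: none, DropOut between blocks, or
DropPath inside them.

Choices the architecture description leaves open, resolved as follows:

- Decoder upsampling uses 2×2 stride-2 transpose convolutions everywhere
  (non-overlapping blocks; matches the final section's stated operator).
- Decoder node widths equal the backbone width of their level, via 1×1
  projection of the concatenated inputs.
- Output head bias initialises to −4.0, the prior log-odds of a rare
  positive class, so the initial prediction is calibrated to "almost no
  dots" instead of 50%.
- Layer-scale gammas start at 1e-6 inside the backbone (the ConvNeXt
  convention, appropriate for a deep pretrainable stack) but at 1.0 in the
  decoder and final section: those shallow sections always train from
  scratch, and near-zero residual branches stall their convergence in short
  runs.
- Batch norm: eps 1e-5, running-statistics momentum 0.01; layer norm eps
  1e-6. DropPath rates grow linearly with block depth up to the configured
  rate. Stem statistics are frozen together with the backbone.

Backbone weights can be loaded from a checkpoint (e.g. converted ImageNet
weights); absent a source the random initialisation is kept and a notice
logged. Freezing the backbone marks its parameters non-trainable; the
optimizer then never touches them.

## Training

Ground truth renders each dot as a 5-pixel cross (centre + 4 axial
neighbours, clipped at borders, unioned on overlap), inflating the positive
class enough for overlap losses to carry gradient. Losses use soft
(probabilistic) counts and smoothing `s = 1e-6` in numerator and denominator:
Tversky `1 − (TP+s)/(TP + αFN + (1−α)FP + s)` (α weights recall; α = 0.5 is
exactly Dice), Jaccard `1 − (TP+s)/(TP+FP+FN+s)`, and pixel-mean BCE. Inputs
are scaled to [0, 1] and standardised with the ImageNet channel statistics.
Augmentation applies rotation up to 90° (bilinear for the image,
nearest-neighbour for the mask so it stays binary) and horizontal/vertical
flips. Large patches are subdivided: random seeded 224×224 crops for
training, a deterministic stride-128 grid for evaluation (3×3 on a 480×480
patch), with per-tile coordinates shifted and out-of-tile dots dropped; tiled
predictions are stitched by per-pixel maximum, which favours recall for the
rare positives.

The optimizer is AdaDelta. The full-scale defaults are ρ = 0.975,
learning rate 0.005, batch 4, input 224×224, with the six-phase curriculum:
460 real samples per epoch throughout (115 patches ×4), generated samples
1071/460/230/115/58/0 per phase, 128 epochs per phase and 1024 in the last,
backbone frozen only in phase 1 (so randomly initialised decoder gradients
cannot destroy pretrained features). Validation IoU is computed at
probability threshold 0.5.

**Desk-scale settings.** The CPU-sized experiment
(`experiments.run_desk_experiment`) trains the `tiny` preset on 64 seeded
128×128 synthetic patches (16 held out) for 40 epochs with Tversky α = 0.6.
Three settings differ from the full-scale defaults, chosen because a
~600-step run occupies a different optimisation regime than a
~100k-step one: AdaDelta's accumulator floor `eps` is raised to 1e-4 and the
learning rate set to 2.0 (with the full-scale values the update magnitudes
stay near zero for thousands of steps — AdaDelta warms up from `sqrt(eps)`),
and augmentation is disabled (the synthetic patches are already randomized;
large early rotations measurably stalled short runs). With seed 1 this
reaches a best held-out F1 of ≈ 0.64 in ~12 minutes on one CPU. Problem
sizes were chosen so the whole suite stays desk-runnable.

## Dot calling

The map is binarized strictly (`value > grey_threshold`; float maps in [0,1]
are scaled by 255 first, so the optimum grey 254 keeps only saturated
pixels). The binary mask's Euclidean distance transform is smoothed with a
0.7-px Gaussian (so flat plateaus of thin clusters yield a single peak),
local maxima at minimum separation 2 px seed a watershed over the negated
distance map (8-connectivity), splitting touching clusters; each cluster with
`area ≥ area_threshold` (0 keeps all) contributes its round-half-up centroid.
The fixed "generation variant" used to harvest natural dots during data
generation is 5×5 circular blur → grey 148 → area 0. The threshold sweep
computes micro-aggregated F1 over a (grey × area) grid, with ties broken
toward smaller area, then smaller grey.

## Matching

Predicted and true dots are matched one-to-one by maximum-cardinality optimal
assignment over edges with distance ≤ tolerance (inclusive; 5.0 px counts),
implemented via `scipy.optimize.linear_sum_assignment` with a large constant
cost on infeasible pairs — the score is invariant to point ordering, unlike
nearest-first greedy matching, which is provided separately for sensitivity
checks. Empty-vs-empty is scored F1 = 1 (perfect agreement on absence);
otherwise 0/0 ratios are 0. Multi-patch results are micro-aggregated (sum
TP/FP/FN, recompute).

## Known limitations

- The numpy NN core is single-threaded and CPU-bound; the `base` network at
  224×224 builds and runs but is impractical to train here. All training
  experiments use the `tiny` preset.
- The synthetic background omits stain variation beyond the yellow→brown dot
  axis, tissue texture and scanner artefacts; results on synthetic data bound
  nothing about real-slide accuracy.
- The exact 480×480 subdivision scheme and any tile-voting used at full scale
  are not specified by the architecture description; the stride-128 grid with
  max-stitching is this package's choice.
- Whether the original post-processing splits touching clusters or merely
  labels components is ambiguous; the splitting watershed is adopted.
- GELU uses the tanh approximation; matching against an exact-erf
  implementation would differ at ~1e-3 relative.
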