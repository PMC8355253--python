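# Methods

## Cascade model and assumptions

The cascade treats slide segmentation as a coarse-to-fine search. The
tile pyramid fixes level 1 as the coarsest level and level `N` as native
resolution; consecutive levels differ by `2^z` per axis (defaults
`N = 3`, `z = 2`, 512-px tiles, so one coarse tile covers a
`4096 × 4096`-px footprint two levels down). Coarser levels are computed
from the next finer level by area averaging (block mean over the pixels
that exist, rounded to uint8); ragged borders are averaged over their
true extent rather than zero-padded, so edge tiles are not artificially
darkened. Border tiles are zero-padded to the full tile size with a
recorded `valid_region`; padded pixels are excluded from attention maxima
and from the assembled mask.

Attention thresholds the per-tile probability maximum at `α` (inclusive,
`≥ α`, default 0.5, identical at every level unless overridden). Two
granularities are implemented: per tile (the literal selection rule, one
bit per tile, an active bit selecting all `2^{2z}` children) and per
unit (each tile divided into `2^z × 2^z` units, a unit's footprint being
exactly one next-level tile). Per-unit is the default; it never selects
more fine tiles than per-tile and produces the same final mask for model
families with the coarse-covers-fine property.

The correctness argument for skipping is conditional: the cascade mask
equals exhaustive level-N inference exactly when every region that the
level-N model scores `≥ α` also reaches `α` somewhere inside its
footprint at every coarser level under that level's model. The package
does not assume this holds for arbitrary trained models — it constructs
model/data pairs for which it holds exactly (below) and verifies the
equivalence bit for bit.

## Synthetic slides

Real cytology cohorts are rarely public, so the generator emulates the
structural regime the cascade targets: large slides (desk-scale defaults
4,096–16,384 px per side rather than the ~10^5-px clinical extreme — all
cascade logic is size-agnostic) with sparse elliptical "lesions"
(default ceiling 1 % lesion pixels per slide) over a textured background.
Lesions are exact point-in-ellipse rasterizations, so area and
containment are brute-force checkable, and the ground-truth mask is by
construction the exact union of lesion supports.

The color model is deliberately idealized: one designated marker channel
is exactly 0 on background and uniform in [220, 255] inside lesions,
with texture confined to the other channels. Consequences:

- a closed-form threshold segmenter on that channel is an *exact* oracle
  at native resolution;
- any area-average block that touches a lesion pixel stays strictly
  positive in the marker channel, so a per-level cutoff schedule
  (`oracle_cutoffs`) gives an oracle family with the exact
  coarse-covers-fine property. For the default `N = 3`, `z = 2` the
  worst-case single-pixel lesion contribution survives two rounds of
  16× averaging and uint8 rounding (220/16 → 14 at level 2, 14/16 → 1 at
  level 1), which the level-1 cutoff (< 0.5) clears. Much deeper
  pyramids would round single-pixel slivers to zero and void the
  bit-exact guarantee; the detectability invariant (lesions with
  semi-axes ≥ `2^{z(N−1)}·2` remain visible after downsampling) is the
  size condition tests rely on there.

What passing these tests does *not* show: robustness to stain variation,
texture-correlated lesions, soft boundaries, or any appearance realism
(nuclei, overlapping cell groups). The synthetic regime isolates the
*bookkeeping* claims (equivalence, work reduction, determinism, metric
arithmetic) from the learning problem.

Randomness: one root seed; slide `k` uses a `SeedSequence((root, k))`
substream so any slide is independently reproducible; the train/test
split (default 68 % / 32 %, rounded to whole slides) uses its own
substream.

## FCN-32s implementation

The segmenter follows the single-stream FCN-32s layout: VGG-style 3×3
convolution blocks (64–512 channels), the first block padded by 100 px so
fc6's 7×7 kernel has context at tile borders, ceil-mode 2×2 max pooling,
fully-convolutional fc6/fc7 with dropout 0.5, a 3-plane score map
(background, lesion, ignore — the lesion plane's softmax mass is the
probability output), one stride-32 kernel-64 transposed convolution
initialized as a bilinear filter, and a symmetric center crop
(`576 = 512 + 2·32` for a 512 input). The published layer table is not
fully self-consistent (its first row repeats the input shape and its
inference column disagrees with its train column for the same input); the
implementation follows the self-consistent train-column arithmetic:
conv1_1 pad-1 (512), conv1_2 pad-100 (710), pools 355/178/89/45/23, fc6
17, upsample 576, output 512. `trace_shapes` reproduces this trace for
any input size and is validated against the built network.

The network is pure numpy: im2col convolutions, argmax-tracked pooling,
inverted dropout, a scatter-add transposed convolution, all with
hand-written backward passes (verified against central finite
differences to ~1e-9 relative error). Training is plain SGD with
momentum 0.9 and L2 weight decay 5e-4 on pixelwise softmax
cross-entropy. Two loss normalizations are exposed: `'sum'` (the classic
unnormalized FCN recipe, paired with the 1e-10 default learning rate)
and `'mean'` (per-pixel average) for desk-scale experiments, where the
reduced-width variant (`width = 0.0625`: channels 4–32, fc 256) with
learning rate 0.01 converges in a few hundred steps on the synthetic
task; larger rates (≥ 0.03) destabilize this small model. With a fixed
seed, training is bit-reproducible (one `Generator` for initialization,
one substream for batching/dropout).

Per-level models are trained independently on level-appropriate
downsampled tiles (mask pixels positive where the footprint's lesion
fraction reaches one half); sharing one model across levels is possible
by passing the same fitted model N times.

## Desk-scale experiment sizes

The verification experiments are sized for a single CPU: the
cascade/dense equivalence suite uses 20 slides of 4,096–8,192 px per side
(level-3 grids of 64–256 tiles); parameter recovery trains the
reduced-width FCN on 19 single-tile 192-px slides (one ellipse each,
semi-axes 40–80 px) for 220 SGD steps and evaluates per-slide Jaccard on
the 9 held-out slides. The 192-px tile size and large lesions are chosen
from the architecture's geometry: a stride-32 single-stream output cannot
trace boundaries finer than roughly half its effective stride, so a
Jaccard of 0.8+ requires lesions a few multiples of 32 px across —
matching the training regime to what the architecture can express, not
to any particular test outcome.

## Numerical choices and edge cases

- Thresholds are inclusive (`≥ α`) everywhere, including the final mask.
- Ties in pooling take the first maximum (row-major); gradients flow to
  that element only.
- uint8 rounding uses numpy's round-half-even; oracle cutoffs sit away
  from representable boundary values.
- `metrics` follows the per-slide (macro) averaging convention by
  default — group means of per-slide metrics need not satisfy
  `J = F/(2−F)`, which holds per slide; pooled (micro) aggregation is
  available by summing counts before `metrics`.
- Degenerate slides: no ground-truth positives → recall NaN and excluded
  from means; no positive mass at all → precision/F/Jaccard recorded as
  0 (flagged); `conventions="strict"` propagates NaN instead.
- Fisher's LSD uses the pooled ANOVA mean square with `N − k` df and no
  multiplicity adjustment, by design; unbalanced groups use
  `SE = sqrt(MSE (1/n_I + 1/n_J))`.
- Throughput arithmetic floors to integers: `⌊w·h/t⌋` px/s and
  `⌊P/(w·h)·t⌋` s.

## Known limitations

- The numpy network is CPU-bound and far slower than a GPU framework;
  full-width training at 512-px tiles is impractical here and untested.
- Bit-exact cascade/dense equivalence is proven only for the synthetic
  color model + threshold oracles; trained models carry no such
  guarantee (a lesion visible only at full resolution can be skipped).
- The generator makes no attempt at cytological realism, and its free
  parameters (lesion count, axes, clustering) are not calibrated to any
  clinical cohort.
- Vendor WSI formats are out of scope; inputs are plain rasters or the
  package's own PNG tile store.
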