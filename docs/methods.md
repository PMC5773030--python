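# Methods

## The rosette model

The simulator is a descriptive (not mechanistic) model of the vegetative
Arabidopsis shoot, expressed as a timed parametric L-system. One module
class per organ: the apex `A(n, a)`, internodes `I`, petioles `P`, and
blades `L`; brackets form lateral branches. A derivation step advances a
global clock by `dt` (default plastochron/10); the apex accumulates age
and, on each plastochron boundary, emits

```
/(θ_n)  I(0.01, n)  [ &(f_ang(n/20))  P  L ]  A(n+1, ·)
```

i.e. a roll about the stem axis by the divergence angle, a short internode
(0.01 model units, giving the compressed rosette stem), and a pitched leaf.
Because the roll is outside the bracket, divergence angles accumulate: at
zero angular spread leaf *k* sits at azimuth `k·137.5° mod 360°` exactly,
which the tests assert.

Leaf placeholders carry `(node, age)`; after the final derivation step they
are expanded into geometry using the growth functions:

* `l_n(t) = X_n · f_lmax(n/20) · f_l(min(age/8, 1))` — blade length;
* `w_n(t, x) = l_n(t) · f_lw(x)` — width at relative midrib position `x`;
* petiole length = 0.5 · blade length; petiole width 0.02 model units.

Ages are measured in plastochrons and normalized by a maturation time of
8 plastochrons, after which a leaf stops growing. Simulations run for
`target_leaf_count` plastochrons plus a 2-plastochron tail so the youngest
leaves are small but visible. Model length units are arbitrary; the render
scale policy (below) removes any absolute-size meaning.

### Stochastic ingredients

All randomness is drawn up front into a `RosetteParams` record (per-plant
provenance, serialized with every generated sample), making
`build_rosette` a pure function:

| draw | distribution | role |
|---|---|---|
| target leaf count | uniform integers 5..20 | development time |
| `X_n` | Normal(1, 10⁻²), truncated at 0 | per-leaf final size |
| `θ_n` | Normal(137.5°, 2.5°) | divergence angles |

"Uniform development time" is realized by drawing the leaf count directly:
this guarantees the stated range and a well-defined integer label. The
label counts every emitted leaf with no visibility threshold (ground truth
must not depend on rendering); an optional `min_blade_length` filter is
exposed for experiments with annotation conventions that ignore small
primordia. Cotyledons are not modeled. Leaf inclination is deterministic
in the node number (`f_ang`), with an optional per-leaf offset hook that
defaults to zero.

### Growth-function defaults

The four curves are control-point curves on [0, 1] interpolated with
monotone piecewise cubics (PCHIP) — smooth, overshoot-free, so lengths and
widths can never go negative between points. The shipped defaults
(`data/default_curves.yaml`) encode the qualitative shapes of measured
rosette allometry: sigmoidal growth `f_l`; final length `f_lmax` rising
from the first nodes to a mid-rosette maximum near n/20 ≈ 0.45 and
declining toward the youngest nodes; an ovate contour `f_lw` peaking at
x ≈ 0.55 with width/length ≈ 0.55; and inclination falling from ~82° of
pitch (old leaves nearly flat) to ~32° (young leaves erect). Users can
substitute measured curves via the YAML serialization, which round-trips
at full float precision.

Node numbers are normalized by 20 (the model's maximum leaf count) to give
the curves a fixed domain.

## Rendering

The renderer is a deterministic software rasterizer with an exactly-nadir
orthographic camera. Per image it draws, in order: the scale ratio
(uniform over 0.5–1.0 of the image side), the background (soil RGB
(110, 80, 55), uniform random RGB, black, or a p = 0.5 mixture — the draw
is recorded in the sample's metadata), and per-leaf brightness jitter
(±10% about the base leaf color). Primitives are projected to polygons
(blade outlines, petiole quads, internode disks) and scan-converted in
painter's order keyed by node number — the attachment order along the
stem — so leaves emitted later, which sit higher and more central, are
composited on top, as a nadir camera sees them. Rasterization happens at
2× supersampling; color is box-downsampled, the mask is a majority rule
per final pixel, and pixels outside the mask are reset to the flat
background color so the background is exactly pure. A sample in which any
blade contributes no visible pixel (fully occluded or sub-pixel) is
rejected and regenerated from the next sub-seed; at 256×256 this affects
a few percent of draws at most.

Blades are stored procedurally (placement frame + length + contour) and
triangulated only on demand (default 24 segments along the midrib, 8
across); because blades are planar, the projected outline polygon and the
projected triangulation rasterize identically, and the outline path is
what makes full 1000-image presets a ~1-minute operation on one CPU.

No shadows, soil texture, pot geometry, or perspective are modeled;
synthetic backgrounds are flat colors.

## Datasets

Presets S1 (12–20 leaves, soil), S2 (5–13, soil) and S12 (5–20, mixed
backgrounds) each default to 1000 images at 256×256. Per-sample seeds are
derived from `(master_seed, index, attempt)` through numpy's splittable
`SeedSequence`, so generation is bit-reproducible and samples are
independent. The on-disk layout (PNG images, PNG masks, `labels.csv` with
`filename,leaf_count`, spec and per-sample parameters in YAML) mirrors the
common phenotyping annotation style, and the loader also accepts external
directories of that shape (leaf-count CSV with or without header; masks
discovered by `_mask`/`_label`/`_fg` suffixes). Train/test splitting is a
seeded permutation with train size `floor(fraction · n)` (ties to test).

## The counting networks

No deep-learning framework is a dependency: layers (same-padded 5×5
convolution via im2col, 3×3/2 max pooling, tanh, dense) carry explicit
backward passes in numpy, which keeps training deterministic given a seed
and single-threaded execution. The *small* architecture is conv–pool ×3
then a linear head; the *large* one is conv–pool ×4, a 1024-unit tanh
layer, then the head. Fixed training constants: L2 penalty λ = 10⁻⁴ on
weights (not biases), static learning rate 10⁻³, 80/20 splits, optional
flips / 10% crop / brightness ±0.1 / contrast 0.8–1.2 augmentation.
Choices the architecture description leaves open are pinned but
configurable: filter counts (32, 64, 64) / (32, 64, 64, 128), Adam with
default moments (plain SGD available), max pooling, batch size 32, 100
epochs with patience-20 early stopping on held-out loss. Predictions are
real-valued; metrics integerize them by rounding half away from zero
(AbsCountDiff, CountDiff, MSE, R², Agreement %), with a real-valued
variant available for transparency. With population (ddof = 0) standard
deviations, `MSE = CountDiff² + CountDiff_sd²` holds as an identity, which
the fuzz tests exploit.

## Experiment drivers and problem sizes

The three drivers (augmentation, generalization with black-background test
preprocessing, interoperability) and the training-set-size sweep run on
user-supplied real data when available; otherwise they substitute labeled
synthetic stand-ins (S1 acting as a narrow-range "real" set) and mark the
rows that genuinely require external photographs as `external data
required`.

Test- and acceptance-scale runs use reduced problem sizes chosen once as
this package's desk-scale conditions: 32×32 inputs, filters (6, 12, 12),
batch 16, no augmentation, 45–500 epochs depending on the check. At that
scale the capacity check (10 images, 500 epochs) reaches training MSE
~2.5×10⁻³, and the {100, 250, 500, 1000} training-size sweep yields median
held-out AbsCountDiff decreasing roughly as 2.9 → 1.0 → 0.6 → 0.4 over
seeds {0, 1, 2} — the values the acceptance tests recompute at run time.

## What passing tests do and do not show

The synthetic generator emulates the geometry, phyllotaxis, size
distribution, scale policy, and background policies of top-down rosette
imagery; it does not emulate leaf serrations/sinuses, color/texture
variation beyond brightness jitter, shadows, moss/water/tray artifacts, or
camera perspective. Statistical checks on the generator (angle/size
recovery, label uniformity, background fractions) validate the stochastic
model itself; learning-behavior checks (overfit capacity, size-sweep
monotonicity, beating the best constant predictor) validate the training
pipeline on synthetic imagery only. None of this certifies accuracy on
real photographs — that requires supplying a real dataset to the
experiment drivers.

## Numerical notes

* Curve evaluation clamps inputs to [0, 1] and returns control ordinates
  exactly at control abscissae (knot round-off is snapped).
* The turtle frame is re-orthonormalized by SVD whenever its Gram defect
  exceeds 10⁻¹⁰; drift stays below 10⁻⁶ over 10⁴ random rotations.
* The apex production credits the firing step's `dt` to the carried-over
  age so the emission period is exactly one plastochron under the default
  `dt = 0.1`.
* Degenerate inputs: empty scenes refuse diameter computation; empty
  manifests refuse training/evaluation; `R²` is 1 for a perfect fit on
  constant truths and NaN for an imperfect one (undefined variance).
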