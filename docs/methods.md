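# Methods

## Frankfurt normalization

The frame construction uses three of the four landmarks.  The text-book
statement "the plane through Vp intersecting line(Lp, Rp)" only defines a
unique point if the plane is taken perpendicular to the line, so the
origin o′ is implemented as the orthogonal projection of Vp onto
line(Lp, Rp).  Two sign conventions are underdetermined and fixed as
follows:

- x-axis direction: Rp → Lp (subject's left = +x).  Classification is
  insensitive to any consistent choice.
- z-axis sign: the normal of plane(Lp, Rp, Vp) through o′ admits two
  signs; we require (o′ − Mp) · z > 0, i.e. z points from the ear line
  toward the cranial vault, away from the orbit.  This is the only role
  Mp plays in the construction.

y = z × x completes a right-handed orthonormal triad; frames violating
orthonormality or handedness by more than 1e−9 are rejected at
construction.

The uniform scale is chosen so that max √(x² + y²) over the cloud equals
exactly 1.  This guarantees every normalized skull fits inside the
global-projection cylinder (ρ = 1.3) with a ≥ 23% radial margin.  The
z-extent is *not* rescaled independently — scaling is uniform — so a
cloud taller than the cylinder (|z| > h/2 = 1.5) would be clipped by the
global projection; a warning is emitted in that case.  For human-skull
proportions (height < 2 × breadth) this does not occur.

The whole pipeline is rigid-invariant: applying any proper rigid
transform jointly to cloud and landmarks changes the normalized output
by < 1e−6 per coordinate (verified as an acceptance check), and
normalization is idempotent to 1e−9.

## Depth projection

**Local (planar).**  The projection plane for each view is tangent to
the cloud (front = min y, left = min x, bottom = min z), so the nearest
surface point reads depth 0.  The raster covers a *square* extent — the
larger in-plane bounding-box side plus a 5% margin per side — so pixels
are isotropic and the breadth/length proportions of the skull survive in
the image; an anisotropic fit to the bounding box would normalize away
exactly the shape signal the classifier uses.  Default resolution
400 × 400 pixels.  When several points land in one pixel the minimum
distance wins (a z-buffer selecting the outer surface).

**Global (cylindrical).**  The azimuth θ of a point is measured from the
start ray — the x < 0 half of the xz-plane, direction (−1, 0) — and
increases counterclockwise viewed from +z.  Pixel indices use floor with
clamping at the top edge (i = H at z = h/2 and j = W at θ → 360° would
otherwise index out of range); row 0 is the cylinder bottom.  Points
outside the cylinder are skipped and counted in the image metadata.
Defaults H = 301, W = 629 match the native panorama size; note the
pixel aspect is not square (2πρ/W ≈ 0.013 per column vs h/H ≈ 0.010 per
row) — the two raster dimensions are free parameters.

**Background handling.**  Raw projections carry a hit-mask; with a
vertex cloud most pixels receive no point.  `smooth` first fills every
background pixel with its nearest hit value (Euclidean distance
transform) and then applies a Gaussian filter (σ = 1 px default), so the
output is a *dense* surface-depth field rather than scattered dots —
smoothing without in-filling would bleed an arbitrary background
sentinel into the surface.  `normalize_intensity` affinely maps hit
values onto [0, 1] (a constant image maps to 0) and renders any
remaining background as 1, i.e. maximum depth; a display-time invert
flag is a rendering concern, not stored in the data.

**Resizing.**  Square local views are resampled bilinearly to the
network side.  The panorama is resized aspect-preserving (long side →
network side, short side proportional, rounded) and zero-padded
symmetrically, the odd remainder going to the high-index side.

Numerical checks: a dense sphere sample (r = 0.8) reproduces the
analytic depth ρ − √(r² − z²) to 1.6e−5 — far inside the discretization
band 3·max(2πρ/W, h/H) ≈ 0.039 — when the analytic value is evaluated
over each row's z-interval.  Near the poles the depth derivative
∂L/∂z = |z|/√(r² − z²) diverges, so the within-row analytic variation
alone exceeds any flat tolerance there; comparing against the row's
analytic depth *interval* is the discretization-correct form of the
check.  Likewise, rotation about z by an integer number of column
pitches shifts the panorama columns exactly; arbitrary angles add
irreducible rebinning noise inherent to any binned panorama.

## Network

Architecture (fixed two-stage layout):

    input (side × side × C, C ∈ {1, 3, 4})
    → [Wide(32) → SE → BN → ReLU → MaxPool 2×2]
    → [Wide(64) → SE → BN → ReLU → MaxPool 2×2]
    → Flatten → Dense(hidden, ReLU) → Dense(1, sigmoid)

- Wide module: 1 × 1 convolution to c₁ channels; two parallel 3 × 3
  branches (standard, and dilated with rate k = 2) consume its output;
  the three results concatenate on the channel axis.  Channel split
  defaults to (out/2, out/4, out/4); both branches use same-padding so
  spatial size is preserved.  The dilated branch has a 5 × 5 effective
  receptive field with exactly the parameter count of the standard
  branch.
- SE block: global-average squeeze, bottleneck C → C/r (ReLU) → C
  (sigmoid), reduction r = 4 — with channel counts of 32 and 64 a
  reduction of 16 would collapse the bottleneck to 2–4 units.  Gates are
  strictly in (0, 1); forcing them to 1 reduces the block to the exact
  identity, which is how the Wide-only ablation variant is built (same
  weight initialization stream, gate short-circuited).
- Batch norm sits after the concatenation, before ReLU.
- Hidden width: 300 for single-projection inputs, 1000 for the fused
  4-channel mode.  Native input side 160; the side is configurable (any
  multiple of 4) to trade resolution for speed.
- Training: Adam (lr 1e−3, batch 16 default) on binary log loss,
  computed on logits for numerical stability.  All randomness (init,
  shuffling) flows from one seed; same seed, same history.

The layers are implemented in numpy (float32, NCHW) with hand-written
backward passes, validated against scipy cross-correlation and
finite-difference gradients.  Convolution runs one batched matmul per
kernel tap, which avoids im2col buffers and is the fastest formulation
at these feature-map sizes on one CPU.

**Batch-norm recalibration.**  Momentum-averaged running statistics need
hundreds of optimizer steps to forget their initialization; after short
trainings inference-mode outputs would diverge wildly from
training-mode behavior.  `train` therefore ends with one accumulation
pass over the training set that sets each BN layer's running statistics
to the exact dataset statistics (computed under training-mode
normalization, as in standard BN recalibration).  When a validation set
is supplied the recalibration runs each epoch so the recorded validation
history is meaningful.

Parameter count for the native local configuration (3 × 160 × 160,
stages 32/64, hidden 300): 30 736 161, dominated by the first dense
layer; verified against closed-form layer arithmetic in the tests.

## Evaluation

Metrics come directly from the confusion counts; any 0/0 ratio returns
NaN as an explicit "undefined" marker (small CV folds can produce empty
predicted-positive sets) rather than a silent 0 or an exception.  Both
class orientations of a report are available via `ConfusionMatrix.swapped`.

Fold splitting wraps scikit-learn's (Stratified)KFold with
shuffle + seed; stratification is on by default in `cross_validate`
because small two-class folds otherwise risk single-class training
splits (a hard error, with advice, when it happens).  Each fold trains a
fresh model seeded from the config seed plus the fold index.

The CV confidence interval treats the K fold accuracies as a sample:
σ̂² = Σ(accₖ − μ̂)²/(K(K−1)) is the variance-of-the-mean estimator (the
quantity under the square root in the interval formula), and c is the
two-sided t quantile with K − 1 degrees of freedom.  Calibration is
checked by simulation: with K = 5 normal draws the 95% interval covers
the true mean in 95% ± 2% of 2000 replicates.  The interval ignores the
between-fold dependence induced by overlapping training sets — a known
bias of all K-fold intervals — so it should be read as a repeatability
band, not an exact frequentist guarantee.

## Synthetic data

The generator emulates what the pipeline needs from a skull scan, not
skull anatomy: a closed convex-ish surface with meaningful landmarks, a
class-dependent shape difference, measurement noise, and arbitrary pose.

- Geometry: superellipsoid |x/a|ᵉ + |y/b|ᵉ + |z/c|ᵉ = 1 with exponent
  e = 2.5 (rounded-box silhouette; purely cosmetic) and default
  half-widths (70, 90, 60) mm — lateral, antero-posterior, vertical —
  matching adult neurocranial proportions.  A Gaussian radial bump
  (8% amplitude) on the front midline stands in for the nasal region so
  the front/back axis is asymmetric.
- Landmarks are placed analytically on the undeformed surface: porions
  at the lateral extremes, glabella on the front midline slightly above
  the equator, orbitale below the front-left orbit; they move jointly
  with the cloud under noise-free pose changes.
- Classes differ only in the cranial-index multiplier m: the lateral
  axis scales by √m and the antero-posterior by 1/√m (volume-neutral);
  class 0 gets 1 − effect/2, class 1 gets 1 + effect/2, with per-sample
  lognormal jitter (sd 0.02).  `effect = 0.3` is strongly separated,
  `0.1` subtle, `0` null.
- Noise: isotropic Gaussian (0.5 mm default, the order of surface-scan
  error).  Pose: a uniformly random rotation plus translation in
  ±100 mm, standing in for arbitrary scanner placement.
- `augment` applies small joint rotations (±5° default) to points and
  landmarks, emulating re-posed re-acquisitions; because landmarks move
  jointly, Frankfurt normalization maps all copies of one skull to
  near-identical clouds — which is itself a test of the
  augmentation/normalization composition.
- Sampling is direction-uniform (surface points along isotropic random
  directions), which is quasi-uniform on near-spherical shapes; 3000
  points default.

What passing tests on this generator do *not* show: robustness to real
cranial topology (orbits, zygomatic arches, foramen magnum, open
sutures), to landmark placement error by human operators, to partial or
damaged skulls, or to scanner-specific artifacts.  The end-to-end
results demonstrate that the pipeline's geometry and learning machinery
are correct and that the classifier recovers a known shape signal — not
that any particular accuracy transfers to real populations.

## Study conditions used by the checks

- End-to-end learning: 50 skulls per class, effect 0.3, fused 4-channel
  input at 80 × 80 (the network's reduced-resolution setting), fivefold
  stratified CV, 8 epochs — enough for convergence at this separation.
  The permuted-label control uses the same pipeline and must land in the
  binomial chance band [0.35, 0.65].
- Ablation: the three variants (full SE-Wide, Wide-only via identity
  gates, plain 3 × 3 convolution baseline) are compared at a
  deliberately *non-saturated* operating point — 30 per class, effect
  0.08, noise 1.5 mm, 40 × 40 input, 16 epochs, five 70/30 splits —
  because at easy settings all variants reach 1.0 and the comparison
  degenerates to ties.  The expected ordering (full ≥ Wide-only ≥
  plain, ties within 1 SD) is a trend statement; seed-to-seed SDs at
  this size are ~0.05–0.15.

## Known limitations

- Meshes are consumed as vertex clouds; faces are never rasterized.
  Very sparse meshes can leave projection pixels dominated by in-fill;
  densely sampled surfaces (≥ ~2000 vertices for the synthetic shapes)
  are assumed.
- The classifier is binary; multi-class ancestry estimation would need a
  different head and metrics.
- Single-threaded numpy training is practical up to ~10⁴ images at
  80 × 80; it is a reference implementation, not a GPU training stack.
- The t interval's independence assumption across folds is approximate
  (see above).
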