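# aninet

Skull ancestry estimation from 3D surface scans, via landmark-normalized
depth projection and a compact squeeze-and-excitation CNN.

## The problem

Forensic anthropologists estimate the population affinity ("ancestry") of
an unidentified skull from its shape — classically by measuring
craniometric indices such as the cranial index (breadth/length ratio) and
applying discriminant rules. This package implements an automated
pipeline that replaces manual measurement with learned features:

1. **Frankfurt normalization.** Four cranial landmarks — left/right
   porion `Lp`/`Rp` (top of the ear canals), glabella `Vp` (midline point
   between the brow ridges) and left orbitale `Mp` (lowest point of the
   orbit) — define a subject-intrinsic frame: the x-axis runs along the
   inter-porion line Rp→Lp, the origin o′ is the orthogonal projection of
   Vp onto that line, the z-axis is the normal of plane(Lp, Rp, Vp)
   signed away from Mp (toward the cranial vault), and y = z × x.  The
   cloud is then uniformly rescaled so its maximum cylindrical radius
   √(x² + y²) is 1, making every skull pose- and size-free.

2. **Depth projection.** The normalized point cloud is rendered as 2D
   depth images: three *local* views (front, left, bottom) drop points
   orthographically onto tangent planes with a minimum-distance z-buffer
   on a 400 × 400 raster; the *global* view surrounds the skull with a
   cylinder of radius ρ = 1.3 and height h = 3 coaxial with the z-axis
   and unrolls it into a 629 × 301 panorama, storing at pixel

       i = ⌊(z + h/2) · H/h⌋,   j = ⌊θ · W/360⌋

   the radial gap L = ρ − √(x² + y²).  Images are in-filled, Gaussian
   smoothed, normalized to [0, 1], resized to the network's 160 × 160
   input (the panorama aspect-preserving with zero padding), and fused on
   the channel axis: 3 channels for local, 1 for global, 4 combined.

3. **Classification.** The classifier stacks two *SE-Wide* stages.  A
   Wide module compresses features with a 1 × 1 convolution and feeds two
   parallel 3 × 3 branches — standard and dilated with rate k = 2, which
   widens the receptive field to 5 × 5 at zero extra parameter cost —
   concatenating all three outputs (32 then 64 channels).  A
   squeeze-and-excitation block then gates each channel with weights
   learned from globally pooled features.  Each stage is followed by
   batch norm, ReLU and 2 × 2 max pooling; a ReLU hidden layer (300
   units, 1000 in fused mode) and a sigmoid unit give the class
   probability.  Training minimizes binary log loss with Adam.

4. **Evaluation.** Confusion-matrix metrics (recall, precision,
   specificity, accuracy, F1), stratified K-fold cross-validation, and a
   symmetric t-distribution confidence interval for CV accuracy:
   μ̂ ± c·σ̂ with σ̂² = Σₖ(accₖ − μ̂)² / (K(K−1)) and c the two-sided
   t quantile with K − 1 degrees of freedom.

Real cranial CT datasets are access-restricted, so the package ships a
**synthetic skull generator**: superellipsoid surfaces with analytic
landmarks, a controllable two-class cranial-index difference, coordinate
noise and arbitrary rigid pose.  Every stage — and the classifier
end-to-end — is tested against it.

The network layers (convolution with dilation, batch norm, SE gating,
pooling, Adam) are implemented in numpy with explicit forward/backward
passes; the package has no deep-learning-framework dependency.

## Worked example

```python
from aninet import SkullShapeParams, generate_dataset, NetworkConfig
from aninet.evaluation import cross_validate, t_confidence_interval
from aninet.pipeline import dataset_to_tensors

# 30 synthetic skulls, subtle class difference (cranial-index gap 0.1)
dataset = generate_dataset(15, effect=0.1, seed=42,
                           base_params=SkullShapeParams(n_points=2000, noise_sd=1.5))
X, y = dataset_to_tensors(dataset, mode="global", side=40)

config = NetworkConfig(channels=1, input_side=40, hidden_units=100,
                       epochs=12, batch_size=8, seed=42)
accuracies, pooled, report = cross_validate(X, y, config, K=5)
ci = t_confidence_interval(accuracies)
print("fold accuracies:", [round(a, 3) for a in accuracies])
print(f"mean accuracy:    {ci.mean:.3f}  (95% CI {ci.lo:.3f}-{ci.hi:.3f})")
print(f"pooled confusion: TP={pooled.TP} TN={pooled.TN} FP={pooled.FP} FN={pooled.FN}")
```

Output:

```
fold accuracies: [1.0, 0.5, 0.833, 0.667, 0.5]
mean accuracy:    0.700  (95% CI 0.430-0.970)
pooled confusion: TP=6 TN=15 FP=0 FN=9
```

At this deliberately subtle effect size the classifier is informative but
imperfect: 70% mean fivefold accuracy, with the wide t interval honestly
reflecting five-fold uncertainty at n = 30.  Raising `effect` to 0.3
(a strong shape difference) drives CV accuracy to 1.0.

The same pipeline is scriptable from the shell:

```sh
aninet synth --n-per-class 15 --effect 0.2 --seed 1 --out data/
aninet project --mesh data/skull_0000.ply \
               --landmarks data/skull_0000.landmarks.json \
               --mode both --out-dir images/
aninet evaluate --manifest data/manifest.json --mode both --folds 5 \
                --epochs 20 --seed 1 --out report.json
```

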