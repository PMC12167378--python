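# Methods

`fluorosep` implements a pattern-guided strategy for doubling the protein
multiplexity of volumetric immunofluorescence: two proteins share one
fluorophore, and the mixed channel is separated computationally. The
package has four scientific components — a contrastive feature extractor,
a max-min pairing solver, a 3D separation network trained on synthetic
mixtures, and a blind-spot denoiser — plus a phantom generator that stands
in for microscope data.

## The model

### Feature-based distance and pairing

Each protein's spatial expression pattern (fibrous, nuclear, punctate,
shell-like, diffuse) is embedded by a 2D CNN: five 3×3 convolution + ReLU +
2×2 max-pool blocks with channels (8, 12, 16, 32, 48), flattened into one
linear layer. Patches of a percentile-normalized stack map to feature
vectors f_p^(i) for protein p. Training is contrastive: with class centers
f̄_p (within-batch means) and ‖·‖ the average of the L1 and L2 norms,

    d_inter = (1/|P|(|P|−1)) ΣΣ_{p1≠p2} ‖f̄_p1 − f̄_p2‖
    d_intra = (1/|P|) Σ_p (1/N_p) Σ_i ‖f̄_p − f_p^(i)‖

and the default loss is `d_intra − d_inter` (a ratio form
`d_intra/(d_inter+ε)` is available via `loss_form="ratio"`). The
difference form is unbounded below — feature magnitudes grow during
training — but Adam's scale-invariant updates keep the geometry stable,
and every downstream use (average-linkage distances, Pearson comparisons,
matchings) depends only on relative distances.

The distance between proteins a and b is the average linkage between their
feature clusters: the mean Euclidean distance over all cross pairs. Note
the training loss uses the mixed L1/L2 norm while pairing uses plain
Euclidean average linkage; both are kept as stated rather than unified.

Pairing 2n proteins into n fluorophore-sharing pairs maximizes the minimum
within-pair distance over all (2n−1)!! perfect matchings
(`G_opt = argmax_G min(d_1 … d_n)`). Up to 16 proteins this is solved
exhaustively with a deterministic tie-break (lexicographically maximal
sorted distance vector, then label order); beyond that,
`bottleneck_grouping` bisects the distance threshold and tests perfect
matchability of the ≥-threshold graph (networkx maximum-cardinality
matching), which yields the same optimal value.

### Synthetic mixing and separation

One separation network is trained per protein pair. Registered
single-protein channels are percentile-normalized (10th percentile → 0,
99th → 1, linear-interpolation percentiles, computed per stack). Training
inputs are linear blends `c_α·I_α + c_β·I_β` with coefficients ≥ 0.01 and
sum in [0.8, 1.2], drawn uniformly over that trapezoid by rejection; this
admits brightness ratios up to (1.2−0.01)/0.01 = 119. Targets are the
normalized single channels with negatives truncated; the mixed input keeps
its negative background. Note the uniform density over the trapezoid is
*not* symmetric in the coefficient sum (segment length ∝ s − 0.02), so
E[c_α + c_β] ≈ 1.0136, not exactly 1.

The network is a 3D U-Net: 3×3×3 conv + ReLU + max-pool encoder (pool
2×2×1 or 2×2×2 per level, configurable schedule), transposed-conv decoder
with channel-concatenated skips, 1×1×1 head to two channels. Loss is
equally weighted L1 + L2. Inference tiles volumes larger than the training
patch with 25 % overlap and linear-ramp blending, and clips outputs at 0
(targets are nonnegative by construction).

### Blind-spot denoising

Preprocessing denoiser: a 2D U-Net consumes the neighbouring z-planes
(centre plane excluded, ±2 planes by default); its output is concatenated
with the centre plane and passed to a blind-spot branch; both branch
outputs feed 1×1 fusion convolutions predicting the denoised centre plane.
Training minimises L1 + L2 against the *noisy* centre plane itself — the
blind spot removes the identity shortcut, so under pixelwise-independent
noise the minimiser is the clean signal.

The blind-spot property (J-invariance: the prediction at a pixel never
depends on that pixel's input value) is enforced structurally: one 3×3
convolution with a structurally zeroed central tap, followed *only* by 1×1
convolutions. Stacking several centre-masked 3×3 layers would silently
break the property — information reaches a neighbour in layer one and
returns to the centre in layer two — which is why depth is added through
1×1 layers. For the same reason, reflective z-padding at stack boundaries
is adjusted so a reflected index can never equal the centre plane (it is
mirrored to the opposite side instead). Both safeguards are covered by
perturbation tests.

## The phantom generator

The generator emulates labeled singly stained z-stacks with five pattern
families: `filament` (constant-speed, angularly persistent random walks
dilated to fibre thickness — GFAP/doublecortin-like), `blob` (soft-edged
solid spheres at Poisson centers — NeuN-like filled nuclei), `punctate`
(bright dots nested in dim nuclear disks — nucleolin-like, deliberately
similar to `blob`), `shell` (hollow sphere rims — lamin-like nuclear
envelopes), and `diffuse` (smoothed positive random field). Object counts
are Poisson with mean `density · volume_µm³ / 1000`; all geometry respects
anisotropic voxels (default (0.2, 0.2, 1.0) µm). Noise is applied last, in
physical order: Poisson shot noise (if enabled), Gaussian read noise, then
a constant offset.

Two realism notes with practical consequences:

- **Haze.** `PatternSpec.haze` adds a faint smooth nonspecific-staining
  background (fraction of object intensity; default 0, preserving the
  exact-background invariant). Real tissue always shows such background,
  and it guarantees the percentile-normalization precondition even when a
  small field draws few objects. In *registered pairs* the haze field is
  shared between the two channels — autofluorescence originates in the
  tissue, not the fluorophore — which also makes the background separable
  in principle; per-channel independent background would be
  information-theoretically unrecoverable from a single mixed image.
- **What a green test does not establish.** Phantoms have no optical PSF,
  no spectral bleed-through, no depth-dependent attenuation, and pattern
  families are cleaner and more stereotyped than real stains. Green
  end-to-end tests establish that the machinery (embedding → matching →
  mixing → separation → metrics) behaves as designed on volumes with the
  stated statistical structure, not that real-tissue performance figures
  are reproduced.

## Metrics

SSIM uses a 7-voxel window per axis, stabilizers K1 = 0.01 / K2 = 0.03,
and the joint data range of the compared volumes; 3D windows on 3D tiles
(a thin-stack 2D path exists via the window-size clamp). PCC is the
Pearson correlation over all voxels and raises on zero variance rather
than returning NaN. The cross-similarity-normalized variants are

    normalized SSIM = (SSIM(x_A,y_A) + SSIM(x_B,y_B)) / (2 (1 + SSIM(y_A,y_B)))

and the PCC analogue — equal to the raw per-channel average when the two
ground truths are orthogonal (cross = 0) and half of it when they are
identical (cross = 1). Pair evaluation tiles all four volumes into
non-overlapping 3D patches (16 by default), scores each tile, averages the
two channels per tile, then aggregates (mean and median); zero-variance
tiles are excluded from PCC aggregation with a logged count.

## Numerical and training choices

- **No deep-learning framework is assumed.** The networks run on a small
  reverse-mode autodiff over NumPy (`fluorosep.nn`): im2col convolutions
  via stride tricks + BLAS tensordot, block max-pooling, kernel-equals-
  stride transposed convolutions, Adam without weight decay. All
  primitives are validated against central-difference gradients.
- Reduced-scale defaults train in seconds-to-minutes on one CPU (64×64
  patches / 16-dim embeddings for features; 3-level U-Net on 48×48×8
  patches for separation). The published full-scale recipes (256×256
  patches, 128-dim embedding, batch 512, lr 3e-3, 100 epochs; 512×512×16
  patches, lr 3e-4, 10 000 epochs; five levels, channels 8–48) are
  preserved as `*.full_scale()` constructors. At reduced scale an "epoch"
  is one optimiser step on one freshly sampled batch.
- The separation optimiser uses cosine learning-rate decay to lr/10 by
  default (`lr_decay="none"` restores a constant rate); at the small
  reduced-scale budgets this stabilises the final iterates.
- Class centers in the contrastive loss are within-batch means; batches
  sample proteins evenly so every class contributes.
- Determinism: every stochastic component (generators, batch sampling,
  initialisation) derives from integer seeds through
  `numpy.random.SeedSequence`; with single-threaded BLAS, loss traces are
  bit-reproducible on a given platform.
- Degenerate inputs fail loudly: constant volumes cannot be
  percentile-normalized, zero-variance images have no PCC, identical
  vectors give the degenerate paired-t convention (t = 0, p = 1) while
  nonzero constant differences raise.

## Known limitations

- The exhaustive matcher is factorial (practical to 16 proteins); the
  bisection solver guarantees the optimal *value* but not the exhaustive
  solver's tie-break among equally optimal matchings.
- The NumPy networks are orders of magnitude slower than GPU frameworks;
  full-scale configurations are API-compatible but impractical on CPU.
- Thin-fibre recovery at reduced scale is the binding constraint on
  unmixing quality: SSIM on filament channels saturates around 0.8 with
  the small training budgets, well below the published full-scale figures.
- t-SNE layouts are for visualization only and are never consumed by the
  pairing decision.
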