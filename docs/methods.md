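# Methods

This note records the models, conventions and design decisions behind
`cropdepth`, in the order the pipeline runs.

## Depth maps and value conventions

All computation happens on 2-D float arrays with intensities in [0, 255],
interpreted as relative (monocular) depth: brighter = closer to the
camera = crop canopy in a top-down shot. 8-bit images are read verbatim;
floating-point arrays are min–max rescaled per image, because relative
monocular depth carries no global calibration (a constant float image maps
to zeros). Masks are {0, 1} in memory and 0/255 on disk; trimaps are
{0, 1, IGNORE} in memory with `IGNORE = 2`, serialized 0/128/255 — 128 is
the conventional ignore index segmentation losses are configured with.
Coordinates are (row, column), origin top-left. Histograms use 256 bins
with round-half-away-from-zero binning.

## Thresholding

**Otsu.** The split objective is evaluated for every threshold T with both
classes nonempty; the smallest maximizing T is returned so runs are
reproducible under exact ties. Binarization is `depth > T`
(strictly-greater) everywhere in the package, with crop as the
high-intensity class.

**GHT.** Implemented from the generalized-histogram-thresholding
formulation: each side of a candidate split is scored by a Gaussian
log-likelihood whose variance is shrunk toward `τ²` with strength `ν`
(inverse-χ² prior) and whose mass is tilted by a Beta(κω, κ(1−ω)) prior.
Defaults are `ν = τ = κ = 0, ω = 0.5` — the released defaults of the
algorithm's reference implementation, which sit at the
minimum-error-thresholding corner of the family. The limit `ν → ∞, τ → 0,
κ = 0` makes the objective proportional to the negative within-class sum
of squares and therefore recovers Otsu; the package exposes it as
`GHTParams.otsu_limit()` (ν = 1e15, τ = 1e-2) and the tests verify exact
agreement with a brute-force Otsu scan there. All quantities are clipped
at 1e-30 before logs so one-sided and empty-variance splits stay finite.

**Gradient-guided thresholding (GGT).** Stages and numerical choices:

- *Depth normalization* subtracts each row's minimum, then each column's
  minimum **of the intermediate** (subtracting the original map's column
  minima could go negative). This removes any additive separable field
  f(row) + g(col) exactly on crop-free ground and is idempotent. It is
  intended for in-field and UAV scenes; the CLI gates it off for `lab`
  manifest records, where the background is already flat.
- *Gradients* use the classic unnormalized Sobel kernels (derivative
  [-1, 0, 1] composed with smoothing [1, 2, 1]; a step of height h yields
  magnitude 4h). Larger odd kernel sizes are built by repeated smoothing
  convolution. Borders are reflective throughout the package
  (edge-repeating reflection).
- *Edges* come from a standard Canny (Gaussian smoothing σ = 1,
  non-maximum suppression, double-threshold hysteresis). The configured
  hysteresis thresholds (defaults 50/125) are expressed on the
  unnormalized Sobel scale and divided by 4 internally to match the
  normalized kernels of the Canny implementation used.
- *Target region* `M_t`: one dilation of the edge map with a square
  structuring element (default 30×30 — a single dilation, not 30
  iterations, since the intent is to bridge broken edge chains slightly),
  followed by filling of enclosed holes. `M_t` is a superset of the
  dilated edges.
- *Gradient levels*: `l = floor(p·g/max g)` clamped to p−1 (the raw
  formula reaches p exactly at the maximum). Level weights `γ_k` are the
  fractions of edge pixels per level; they sum to 1 whenever any edge
  pixel exists.
- *Weighted histogram*: `R_T` sums `γ_{l_ij}` over edge pixels with
  rounded normalized depth T — the sum runs over all edge pixels, not
  only those inside `M_t`; the target region gates only the transformed
  map. `S` is the cumulative sum of `R` rescaled to end at 255, hence
  monotone.
- *Sigmoid fit*: bounded least squares of `255/(1+e^{−a(T−b)})` over all
  256 samples of S, with a ∈ (0, 5], b ∈ [0, 255]; initialized at
  a₀ = 0.1 with b₀ at the first T where S crosses 127.5, plus two spread
  restarts (b₀ = 64, 192); the lowest-residual fit wins. The sigmoid's
  slope is maximal at its midpoint, so the threshold is `T* = round(b)`.
- *Binarization*: the monotone map `T ↦ S_T` is applied to the normalized
  depth, pixels outside `M_t` are zeroed, and the mask is
  `transformed > T*`.
- *Fallbacks*: if a stage degenerates (zero gradient, no edges, empty
  weighted histogram, fit failure) the call falls back to Otsu on the
  original depth map and names the failed stage in the diagnostics; a
  depth map that is degenerate even for Otsu (single intensity) raises.

## Mask refinement

The guided filter follows the local-linear-model recurrence (per window:
`a = cov(I,p)/(var(I)+ε)`, `b = mean(p) − a·mean(I)`, then window-averaged
coefficients), with box means over (2r+1)² windows; guidance is rescaled
to [0, 1] (RGB via luma). With constant guidance — or as ε → ∞ — it
reduces exactly to a double box mean, which the tests exploit as an
independent oracle. The joint bilateral filter multiplies a spatial
Gaussian (σ_space, default 15) by a range Gaussian on the guidance
(σ_color, default 25, in native intensity units); the window is a square
of side 2·(d//2)+1 for diameter d (default 20). As σ_color → ∞ it reduces
to truncated spatial Gaussian convolution. Both filters are convex
averages, so [0, 1] inputs stay in [0, 1]. `refine_mask` casts the binary
mask to [0, 1], filters, and rebinarizes at strictly > 0.5 (majority
vote — the natural contract for a probability-like map; mIoU needs binary
masks).

## Two-stage self-training

The trimap keeps the pseudo label where stage-one prediction and pseudo
mask agree and writes IGNORE where they disagree, so the IGNORE count is
exactly the Hamming distance between the two masks. Stage two must
warm-start from stage one; backends that cannot are rejected. The toy
backend is a per-pixel logistic classifier over depth-derived features
(depth, normalized depth, 9×9 local mean, each scaled by 1/255), trained
with a fixed budget of full-batch gradient-descent epochs (default 150,
learning rate 2.0, L2 1e-4, zero initialization) — deterministic by
construction. The finite budget is deliberate: a fully converged convex
fit is almost invariant to moderate label noise, which would make the
two-stage comparison vacuous; a fixed-budget learner both feels the noise
and benefits measurably from the cleaned stage-two labels.

## Synthetic scenes

A scene is `clip(background + β_r·i + β_c·j + Δ·profile + noise, 0, 255)`
where `profile` is a union of raised plateaus with 1-px cosine shoulders
(smooth shoulders give the strong boundary gradients the edge-weighted
histogram relies on; the ground-truth mask is the full support, shoulder
included). Defaults: 192×192, 4 blobs of radius 16–28 px, Δ = 90,
background 40, σ = 1.5, no bias — a flat-ground condition under which the
depth histogram is two well-separated populations and plain Otsu recovers
the ground truth to mean IoU ≈ 0.96 (the residual loss is the outer
shoulder ring, whose contrast vanishes by construction). The shoulder is
kept at 1 px precisely so that this two-population property holds; wider
shoulders put appreciable mass between the modes and degrade every
histogram splitter. `SceneSpec.biased()` is the in-field condition:
background 20, Δ = 80, row/column slopes 0.45/0.1, making the background
span roughly the same range as the crop contrast — there bimodal
splitters cut the ramp itself (mean IoU ≈ 0.35) while the
normalization-based pipeline is unaffected (≈ 0.97). One
`numpy.random.Generator` seeded from `SceneSpec.seed` drives each scene;
batches use consecutive seeds; values are quantized only when written to
PNG. An optional coverage target re-samples blob placements, adapting the
blob count on the Boolean-model (λ) scale, until the mask area is within
±0.05 of the target.

What the generator does *not* emulate: leaf-level canopy texture,
occlusion between plants, depth-model artifacts other than separable
bias and i.i.d. noise, and RGB realism (the RGB render is cosmetic).
Passing the simulation studies therefore demonstrates the algorithmic
contracts — bias removal, edge-weighted thresholding, distillation,
guided refinement — not field-ready accuracy on real imagery.

## Study sizes and conditions

The simulation studies use 20 scenes per condition at 192×192, which keeps
the full suite and the acceptance script in the seconds-to-minutes range
while the pooled statistics are stable to ~0.001 across seed bases.

The distillation study runs on scenes with a 0.6 coverage target (12
blobs) and 10% uniformly flipped pseudo-label pixels. Coverage matters
for the sign of the flip bias: below 50% coverage most flips turn
background into foreground, which *helps* a linear per-pixel model by
offsetting its intrinsic under-segmentation of the faint shoulder ring —
an artifact of the toy model's hypothesis class, not of distillation. At
~60% coverage the net flip mass removes foreground, stage one is
genuinely degraded, and the trimap-cleaned stage two recovers toward the
clean-label optimum. High canopy coverage is also the regime where
depth-based labeling is hardest in practice, which makes it the right
stress condition for the loop.

## Known limitations

- The GGT threshold `round(b)` is applied to the S-transformed depth;
  because S is monotone this is equivalent to an intensity threshold at
  S⁻¹(b), a deliberate, documented reading of the sigmoid-inflection rule.
- The joint bilateral filter is the exact O(H·W·d²) loop, adequate at
  toolkit scales; no O(1) approximations are provided.
- Pooled mIoU assigns IoU 1 to a class absent from both prediction and
  ground truth everywhere — unreachable in practice at dataset scale, but
  the convention matters for tiny fixtures.
- The toy backend is linear per pixel; it exists to exercise the
  orchestration (ignore semantics, warm start, determinism), not to
  approximate a segmentation network's capacity.
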