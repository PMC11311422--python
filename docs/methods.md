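# Methods

## The image model

A color fundus photograph is modeled, inside the eye region (ROI), as a
smooth per-channel background illumination surface plus localized
foreground deviations:

    c(x, y) = BB_c(x, y) + gap_c(x, y),   c ∈ {R, G, B}

`BB_c` varies slowly (vignetting, uneven illumination, boundary
reflection); the *gap* is the signal of interest — negative under vessels
and hemorrhages, positive under exudates and the optic disc. The pipeline
estimates `BB_c`, replaces it with a constant mid-grey baseline, stretches
the remaining contrast under constraints, and restores color from stored
per-pixel channel ratios. The model is strictly additive; no
multiplicative (retinex-style) correction is attempted.

## Stages

1. **ROI detection.** Pixels whose channel-mean exceeds `threshold`
   (default 20 of 255; fundus surrounds are near black) are kept, reduced
   to the largest 4-connected component, hole-filled, and unioned with
   their left-right mirror so a reflection-clipped ROI is completed rather
   than shrunk. Union (not intersection) is deliberate: clipping artifacts
   remove ROI pixels, they do not add them.
2. **Ratio storage.** `R/G` and `B/G` are stored per pixel from the
   *original* channels, with green floored at `epsilon = 1` level so the
   ratios stay finite and bounded by 255.
3. **Pre-filter.** Each channel is smoothed by a 3×3 average restricted to
   ROI members (off-ROI neighbors are excluded from sum and count), which
   steadies values along the ROI border without bleeding in the black
   surround.
4. **Background estimation.** Masked normalized convolution: at each ROI
   pixel the kernel is applied to the ROI members of its footprint and the
   surviving weights renormalized to unit sum. Out-of-image samples are
   treated exactly like out-of-ROI samples. This reproduces constants
   exactly everywhere — the property that anchors the later baseline shift
   at the border. Per-pixel renormalization breaks separability, so the
   full 2-D kernel is applied (as a numerator and a denominator
   convolution). The result is finished with the 3×3 masked average.
5. **Luminosity adjustment.** `A_c = clamp(128 + c − BB_c, 0, 255)` on the
   ROI. The 128 baseline is the method's constant; clamping (the
   implementation's choice — the arithmetic is done in signed reals first)
   keeps the equalization stage in an 8-bit range. The *full-information
   green* pools all three gaps: `AGF = 128 + Σ_c (c − BB_c)`, exploiting
   the co-variation of the red and blue gaps with green.
6. **Constrained equalization.** A single-tile, ROI-wide, contrast-limited
   equalization of `AGF`: the 256-bin ROI histogram is clipped at
   `clip_factor × pixel_count / occupied_bins` (factor 2 by default) with
   one-pass uniform redistribution of the excess; the cumulative
   distribution is mapped to [0, 255]; then a left-to-right sweep enforces
   that distinct levels stay distinct and no consecutive-level gap
   shrinks. If the sweep overshoots 255, the expansion above the input
   gaps is shrunk by the largest common factor that fits (dropping the
   anchor as a last resort — always feasible because the input span is at
   most 255). The clip denominator is *occupied* bins, not 256: after
   adjustment the histogram is concentrated near the baseline, and a
   256-bin uniform limit would never bind.
7. **Color restoration.** `R = r/g·EG`, `G = EG`, `B = b/g·EG`, rounded
   half-away-from-zero and clamped; extreme products saturate rather than
   rescale, accepting a minor hue shift at specular pixels.

## Kernels

The production kernel is a 41×41 binomial (half-width 20), built by exact
integer Pascal-row accumulation and outer product, then rescaled so the
peak is 100, multiplied by the flattening factor α, and floored at 1. The
order (scale → α → floor) matters: with α = 0.01 the peak becomes exactly
1 and the whole kernel collapses to a box filter. α = 0.1 is the default —
flat enough to level foreground structure, peaked enough to track the
illumination. α is accepted on (0, 1]; coefficients are kept as reals
throughout (no quantization). Baselines in the same framework: a 41×41
Gaussian (σ = 5, peak scaled to 10, floored at 1) and a 41-window sliding
median over ROI members, computed by sweeping a 256-bin histogram with
integral-image counts (lower median on even member counts).

## Metrics

Luminosity is mean CIELAB L* (sRGB → XYZ → L*a*b*, D65) over the ROI.
Contrast is a three-resolution global contrast factor: lightness
(L*/100) and the ROI mask fraction are downsampled by 2×2 block averaging
(a superpixel is in-ROI when its fraction exceeds ½); per level, local
contrast is the mean absolute lightness difference against in-ROI
8-neighbors, the level contrast is its mean over in-ROI pixels, and the
GCF is the weighted sum with weights 0.12, 0.142, 0.154 (finest to
coarsest). Gains are plain relative changes in percent; a summary row
averages the before/after columns and recomputes the gains from those
averages, so it satisfies the same formulas as each row.

## The phantom generator

Phantoms define the test conditions: 500×700 frames, a disc ROI at 94% of
the half-height, background base RGB (120, 75, 38) — mean lightness ≈ 36
L-units, the dim degraded class this method targets, with the fundus
ordering R ≥ G ≥ B — a 40-level linear gradient, an optional 60-level
Gaussian reflection bump centered on the ROI border, eight random-walk
vessel strokes (width 3, 40 levels dark), six exudate discs (radius 5,
50 levels bright; together ≈ 8% foreground coverage at full size), and
clipped Gaussian noise (σ = 1). All randomness flows from one
`numpy.random.default_rng(seed)`, so a seed fixes the phantom bit-exactly
across runs and platforms.

What the phantoms do *not* emulate: branching vessel trees, the optic
disc, texture, chromatic noise, JPEG artifacts, and steep-edged
reflections (which the method intentionally treats as foreground).
Passing tests therefore validate the pipeline's arithmetic and its
behavior on smooth illumination — not clinical image quality.

## Numerical choices and degenerate inputs

- Constant-in-ROI channels are reproduced by the background estimator to
  machine precision (asserted at 1e-9; float summation order precludes
  bit-exactness).
- A single-level ROI histogram maps to itself (no spread is possible
  without violating the level-count constraint).
- A green value of 0 contributes ratios `R/1`, `B/1` via the epsilon
  floor; an all-background pixel with `EG = 0` recombines to black.
- Sliding-median ties on even member counts take the lower median.
- The ROI threshold, baseline, clip factor, α, σ and kernel size are all
  exposed as CLI flags; defaults are the values above.

## Test problem sizes

Unit and property tests run on 12×12–20×20 random mask/image pairs
(oracle comparisons), 160×220 phantoms (stage-level behavior), and
500×700 phantoms for pipeline-scale properties (baseline recovery,
filter-family similarity, second-pass damping). The eight-phantom
three-filter directional sweep runs at 250×350; the enhancement gains it
asserts are scale-robust in sign.

## Known limitations

- On few-level synthetic histograms the constrained equalization
  redistributes clipped mass widely, so enhancement is not idempotent:
  a second pass still moves mean lightness (it damps — the second change
  is smaller than the first — but exceeds 5%). Real fundus histograms
  occupy far more levels and are closer to a fixed point.
- The ROI detector assumes a single roughly circular eye region; montage
  or multi-field images are out of scope.
- Steep-edged reflections and border-touching exudates are
  indistinguishable from foreground/background respectively, a property
  inherited from the smooth-background model itself.
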