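# Methods

`pigpen` implements an occlusion-aware preprocessing and early-fusion
pipeline for detecting pigs with a **static camera**, together with the
synthetic study harness needed to exercise it end-to-end on a CPU. This
note documents the model, the parameters that matter, what the simulator
does and does not emulate, and the design choices made where the design
was genuinely open.

## The static-camera preprocessing phase

A fixed camera watching a pen affords two pieces of one-time,
per-environment knowledge:

* a **background plate** `f_bg` — the scene without animals (supplied as an
  image, or estimated with the temporal-median fallback
  `estimate_background`);
* an 8-bit **depth map** `f_depth` of the plate with the *higher = closer*
  convention, from which pen infrastructure (feeders, pipes, rails) that
  sits nearer the camera than the floor is segmented.

Both are computed once per environment and stored in a `BackgroundModel`;
every subsequent frame reuses them. Depth estimation and background
inpainting are deliberately *inputs* here (provider interfaces): any
offline estimator can produce them, and the simulator produces exact ones.

## Background-suppressed image generation

Per frame `f`:

1. `d = max_channel |f − f_bg|` (widened integer arithmetic, no 8-bit
   wraparound; the per-pixel channel maximum keeps the strongest change in
   any channel — the reduction rule for color inputs is our choice, as the
   scalar formulation leaves it open);
2. Otsu's threshold `t` on the 256-bin histogram of `d`, maximizing the
   between-class variance `w0·w1·(μ0−μ1)²` with foreground `d > t`,
   ties broken toward the smallest maximizing `t`, and a constant image
   returning its single value (empty foreground);
3. foreground mask `m = 255·[d > t]`;
4. background-suppressed image: `f` where `m ≥ 128`, black elsewhere.

The output preserves the animals' original texture while deleting all
background content. The threshold is recomputed per frame (the difference
image depends on the frame); only the plate is per-environment.

The `≥ 128` mask test is adopted over the strict `> 128` variant that
also circulates; the two differ only for mask value exactly 128, which a
{0, 255} mask never produces.

## Facility masking and the image fuser

Otsu's threshold on the depth map separates the two depth populations;
pixels strictly above it (closer) form the **facility mask**, binarized to
{0, 255}. A uniform depth map yields an empty mask — open pens with no
occluding infrastructure are a first-class state. The fuser then paints
facility pixels **white (255) in both network inputs**: the
facility-applied input image and the facility-applied background-suppressed
image. White-out equalizes heterogeneous facility textures across
environments, so a detector meets the *same* surrogate texture at train
and deployment time. Both views, stacked, are the detector's dual input
(`FusedPair`).

## Dual-stream fusion stem

The stem replaces a detector's first convolution layer and consumes both
views (each `B×3×H×W`):

1. each view passes its own stride-2 3×3 convolution (3 → C channels);
2. the suppressed branch becomes an attention map: SiLU, then SoftMax
   along the **channel axis** at each location, scaled by the multiplier
   **λ** (default 2). Channel-axis normalization is our choice where the
   axis is open: it makes the attention mass per position independent of
   image size, so λ has a scale-free meaning. The map sums to λ along the
   SoftMax axis everywhere by construction;
3. the attention modulates the input-branch features element-wise;
4. the modulated and input-branch maps are stacked on a new depth axis
   (depth 2) to a 5D tensor `B×C×2×H/2×W/2` and fused by a 3×3×3 3D
   convolution with stride (1, 2, 2) and padding (1, 1, 1) — the depth
   survives the convolution so that the subsequent **max pool over depth**
   is a meaningful reduction step — giving `B×C×H/4×W/4`.

Ablation fusions share the shape contract: element-wise addition followed
by stride-2 spatial max pooling, and channel concatenation followed by a
stride-2 2D convolution back to C.

Because the stem outputs stride 4 where a baseline stem conv outputs
stride 2, every downstream layer runs on feature maps with a quarter of
the pixels. Conv FLOPs (`2·Hout·Wout·Cout·(Cin/g)·Kh·Kw`, one
multiply–accumulate = 2 ops; 3D adds `·Dout·Kd`) are linear in
`Hout·Wout`, so the downstream cost divides by exactly 4. On the bundled
reference audit backbone (5 stages, 3 convs per stage, widths
32–512, 640×640 input) the total ratio is 0.294; the stem itself is more
expensive than a single conv (two branch convs plus the 3D conv), which is
why the ratio is above 1/4 and why the saving shrinks for very small
backbones. The accountant counts convolutions only — activations, pooling
and normalization have no agreed formula and are excluded.

Weights use seeded He initialization; everything is float32 NumPy with
reverse-mode autodiff (`pigpen.nn`), fully deterministic per seed.

## The synthetic pen simulator

`scene_synth` emulates the geometry that matters to the pipeline, not
photorealism:

* low-frequency background texture (Gaussian-smoothed noise, smoothing
  scale 8 px, base RGB (92, 72, 58) for the training pen) plus fine
  per-channel grain and sensor noise (σ = 2 intensity levels);
* bright facility structures — a feeder block and two pipes — drawn *over*
  the animals (facilities occlude), present in the plate, and at depth 220
  versus floor depth 40 in the depth plate;
* 4 elliptical animals per scene, semi-axes 10–20 px, speckled texture at
  gray 185 ± 18 with a slight pink tint, placed by seeded rejection
  sampling that keeps blobs mostly apart;
* ground truth: an animal is labeled only when **more than 20%** of its
  pixels are visible under the facility raster (pixel-mask visibility, not
  box-area overlap — facility bars are thin, so box-area overlap would be
  misleading). The inequality is strict: exactly 0.2 is excluded.

The *unseen* environment changes the floor color/texture (base RGB
(152, 148, 132), scale 5 px) and rearranges the facility layout. Both
environments contain the same *kinds* of structures (feeder block,
horizontal pipe, vertical pipe), as real pens do; what changes is where
they are. `(config, seed)` determines every emitted byte; the plate
depends only on the config, so all frames of one environment share it, as
a static camera requires.

What the simulator does **not** emulate: perspective and lens distortion,
illumination changes and shadows, animal contact/huddling, motion blur,
and imperfect (inpainted/estimated) plates. Passing tests therefore show
that the pipeline's mechanisms behave as specified and that the expected
generalization ordering emerges under controlled domain shift — not that
the absolute accuracy numbers transfer to farms.

## Toy detector and the directional experiment

The detector is deliberately minimal: the interchangeable stem (baseline
single conv vs. dual-stream), a body of stride-2 3×3 convolutions
(channels 4 → 16 → 32), and 1×1 heads predicting per-cell objectness and
box parameters on a 10×10 grid (stride 16 at 160×160). The baseline body
starts at H/2 — twice the dual stem's resolution — and appends one extra
stride-2 block at the end so both variants predict on the same grid; the
body *layer list* is identical, isolating the stem and preprocessing as
the difference. With the default configuration the dual-stem variant costs
fewer conv FLOPs than the baseline (6.9 vs. 8.8 MFLOPs per 160×160
frame).

Training (Adam, lr 4e-3, batch 8, 90 epochs, binary cross-entropy on
objectness with positive cells up-weighted 8×, L1 box loss weight 5)
includes two measures that matter for a static camera:

* **seeded flip augmentation** — every training image shows the one fixed
  facility layout, so without flips the detector memorizes absolute
  structure positions and fails on any new layout, for every variant;
* **facility-aware target assignment** — an animal is assigned to the
  least-facility-covered grid cell inside its box (offsets decode as
  `2·sigmoid − 0.5` cells, so off-center assignment stays representable).
  A box center hidden behind a white-out carries no observable evidence,
  and anchoring positives there teaches the detector that pure white is a
  pig. The rule uses only the ground-truth box and the environment's
  facility mask — exactly the information the preprocessing phase
  provides — and applies to all variants alike.

The directional experiment trains each variant on 24 images of the seen
pen and evaluates AP50/F1 (pooled, all-point-interpolated PR, IoU ≥ 0.5
one-to-one greedy matching) on 12 images of each environment, over three
seeds; these sizes are the package's CPU-scale defaults. The median
unseen AP50 of the full pipeline (suppression + facility masking +
dual-stream stem, λ = 2, 3D-conv fusion) exceeds the raw-frame baseline by
an order of magnitude (≈ 0.2 vs. ≈ 0.02 on the default seeds), while the
baseline's seen-environment score shows the gap is a domain-shift failure,
not a capacity one.

A finding specific to the simulator is worth stating plainly: the variant
*without* facility masking transfers best of all (median unseen AP50
≈ 0.5). The simulator's background plate is exact, so background
subtraction already deletes facilities from the suppressed view perfectly,
and painting them white reintroduces environment-specific bright structure.
With real estimated/inpainted plates the suppressed view retains facility
residue and misses occluded-animal fragments — the regime in which
facility masking is reported to pay on real farms. The toolkit ships both
variants so the trade-off is measurable rather than assumed.

## Numerical choices and degenerate inputs

* Otsu: first (smallest) maximizer on ties; constant image → its value.
* Masks are {0, 255}; every mask test uses the ≥ 128 convention.
* Matching: descending confidence, ties by input order; each detection
  claims the unmatched ground truth with the highest IoU if ≥ threshold.
  Greedy matching can in principle differ from the maximum assignment;
  tests verify equality against an exhaustive oracle on random instances.
* AP uses all-point interpolation (`p_interp(r) = max_{r'≥r} p(r')`);
  precision/recall use the 0-when-denominator-0 convention.
* FLOPs are exact integers until the final division by 1e9.
* Attention with λ = 0 is exactly zero; uniform inputs give λ/C per
  channel.
* NMS is greedy with IoU > 0.45 suppression; detection boxes are clipped
  to the image.

## Known limitations

* The detector is single-scale and single-class; it ranks preprocessing
  variants but is not a production pig detector.
* The FLOPs accountant ignores non-conv layers, so its totals are not
  comparable with tools that count them.
* The simulator's domain shift is one axis (appearance/layout); viewpoint
  and density shifts seen across real farms are not modeled.
* Absolute AP50 values depend on the toy training budget; only orderings
  between variants are meaningful.
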