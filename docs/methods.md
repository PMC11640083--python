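# Methods

## Pipeline model

The package grades Parkinsonian gait severity from the *shape of
movement over time* rather than from appearance: every walking clip is
reduced to Skeleton Energy Images (SEIs), pixel-wise means of K = 17
consecutive height-normalized stick-figure rasters, and the grading is
ordinary 4-way image classification on those SEIs.  Seventeen frames at
the 10 fps sampling rate cover roughly 1.5 gait cycles, so every limb
passes through its full swing inside one kernel; the stride-1 rolling
kernel turns a segment of N frames into N − 16 overlapping SEIs, which
both amplifies the dataset and presents each joint trajectory at 17
phase offsets.

Key processing rules, in pipeline order:

- frame sampling on the half-open grid `start + k/fps, k = 0, 1, …`
  (aligned to the segment start), default 10 fps;
- segments with fewer than 17 sampled frames are discarded;
- a pose joint is valid only with confidence strictly above 0.5; a
  frame missing any of the 12 body joints is dropped, and sequences
  left with fewer than 17 frames are discarded;
- normalization scales each pose isotropically to a 360 px vertical
  extent and centers its bounding box on the canvas;
- the key-frame variant anchors kernels only at frames whose
  inter-frame difference strictly exceeds 1.5× the mean of up to 10
  preceding differences (frame 0 is always a key frame); a key frame
  followed by fewer than 16 frames, or whose window covers a
  pose-rejected frame, contributes nothing.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| sampling rate | 10 | frames/s | temporal resolution of SIs |
| kernel K | 17 | frames | SEI window, ≈1.5 gait cycles |
| confidence threshold | 0.5 | probability | joint validity (strict >) |
| target height | 360 | px | pose normalization extent |
| canvas | 400×400 | px | raster size (~11% margin for limb swing) |
| line width | 3 | px | stroke thickness |
| key-frame window / factor | 10 / 1.5 | frames / ratio | difference rule |
| split ratios | 8:1:1 | — | train/validation/test |
| learning rate / batch | 5·10⁻⁵ / 64 | — | training protocol |
| min epochs / patience | 25 / 20 | epochs | early stopping on val loss |

Canvas size and line width are package choices (the normalization
height is the pipeline's fixed point; the canvas merely has to contain
the figure during limb swing), exposed in `RenderConfig`.

## Numerical choices

- **Binary strokes, no anti-aliasing.**  A pixel is dark iff its center
  lies within `line_width/2` of a bone segment (distance-to-segment
  thresholding, not Bresenham).  Single-frame rasters are therefore
  two-valued, so intermediate SEI gray levels arise from temporal
  averaging only, and rendering is exactly symmetric under mirrored
  poses.  A `1e-9` slack on the squared-distance comparison keeps
  pixels on the exact stroke boundary stable under float noise, making
  renders bit-identical under input translation and uniform rescaling.
- **Bone list.**  Arms (shoulder–elbow–wrist ×2), legs
  (hip–knee–foot ×2), shoulder girdle, pelvis, and the two ipsilateral
  shoulder–hip trunk edges — 12 edges over 12 joints, headless.
- **SEI mean.**  Computed as `S₀ + Σ(Sₙ − S₀)/K` (baseline-subtracted),
  which is exact when all frames are identical and agrees with the
  naive per-pixel mean to < 10⁻¹² otherwise.  Rolling windows reuse the
  same routine, so a key-frame SEI is bit-identical to the rolling SEI
  with the same start index.
- **Split remainder rule.**  Validation and test each get ⌊N/10⌋
  records; when N is not divisible by 10 the remainder bumps validation
  first, then test, by at most one each, and the rest stays in train.
  For N divisible by 10 this is exact (23,580 → 18,864/2,358/2,358).
- **Oversampling order.**  Balancing *before* splitting (the
  replication protocol of the balanced-dataset experiment) lets
  duplicates of one image land in both train and test, which inflates
  test accuracy.  The package default elsewhere is train-only
  balancing (`balance_training_split`); the experiment-4 runner keeps
  the pre-split order deliberately.
- **Early stopping.**  Training stops when the validation loss has not
  strictly improved for 20 consecutive epochs, never before epoch 25;
  the retained checkpoint is the global argmin of the validation loss
  (on an early-stopped run it necessarily lies in the final patience
  window).  There is no epoch cap in the protocol; a configurable
  safety cap (default 500) exists as an engineering guard and logs
  loudly when hit.
- **CNN head.**  Convolutional blocks are conv(3×3) → batch norm →
  ReLU → 2×2 max pool → dropout with widths 16…256 (…512 for the
  6-block variant), followed by *global average pooling*, a 256-unit
  hidden layer and the 4-way head.  Global pooling (rather than
  flattening) keeps the parameter count strictly increasing with depth
  and makes the CNN input-size agnostic.  ResNet-18/34 and ViT
  tiny/small/base follow their standard published configurations
  (patch 16 for the ViTs) with a 4-way head; SEIs are grayscale, so the
  CNN takes one channel and ResNet/ViT replicate it to three.
- **Network input scaling.**  Models see stroke intensity `1 − pixel`
  (figure positive on a zero background); feeding the nearly constant
  white-background raster directly conditions training poorly.
- **Framework.**  The layers (im2col convolution, batch/layer norm, max
  pool, dropout, residual blocks, multi-head self-attention) carry
  hand-written backward passes in float32, verified against central
  finite differences; training is fully seeded, so identical seeds give
  identical curves and weights.

## The synthetic gait generator

A sagittal-plane kinematic chain stands in for a walking subject: the
pelvis is the root (with a small vertical bob at twice the cadence),
the trunk is a rigid segment tilted forward by `trunk_lean`, thighs and
shanks swing as phase-offset sinusoids at the given cadence with
amplitude set by `step_length`, the swing-phase foot lifts by
`foot_lift`, knees carry a constant severity-linked flexion (`crouch`),
arms swing contralaterally with amplitude `arm_swing`, and Gaussian
jitter of standard deviation `tremor_jitter` perturbs every coordinate.
All 12 joints are emitted at confidence 1.0; everything is
deterministic given the seed.

Severity profiles (defaults): trunk lean 0/4/8/12°, crouch 0/8/16/25°,
arm swing 35/25/15/6°, cadence 1.0/0.85/0.70/0.50 cycles/s, step length
0.50/0.40/0.30/0.18 of leg length, foot lift 0.15/0.12/0.08/0.04,
jitter 0.3/0.8/1.4/2.0 px.  Lean increases, and arm swing and cadence
decrease, strictly with severity — the profile constructor enforces the
ordering.  Per-subject variation multiplies each control by a bounded
±5% factor, small enough to preserve the between-class ordering.  A
"hard" profile with narrower gaps exists for robustness testing.

Two geometric points deserve a note.  First, under bounding-box height
normalization a strongly tilted trunk *raises* the dark-pixel center of
mass (the diagonal trunk stroke compresses into fewer, higher rows), so
very large lean angles would invert the expected "stooped figures sit
lower" signature; the defaults therefore keep lean in the clinically
typical early-stage range (≤ 12°) and let crouch and reduced foot lift
carry the posture signature.  With these defaults the mean vertical
center of mass of SEI strokes is measurably higher for the normal class
than for the severe class, as the posture reasoning predicts.  Second,
the walker is rendered treadmill-style (no net translation); the
skeleton normalization makes this equivalent to a tracked subject.

What the generator does *not* emulate: camera perspective and parallax,
occlusion and pose-estimation noise structure (confidences are always
1.0 unless explicitly scripted), multi-person scenes, freezing-of-gait
episodes, turning and orientation transitions within one segment, and
any biomechanically validated joint dynamics.  Passing tests on
synthetic cohorts therefore demonstrates that the pipeline's plumbing,
arithmetic and learning machinery work and that severity-correlated
kinematics are recoverable from SEIs — not that the classifiers reach
any particular accuracy on clinical video.

## Desk-scale (reduced) budget

The full protocol — 224 px inputs, published widths, learning rate
5·10⁻⁵, open-ended epochs — is sized for GPU training on ~17k SEIs.
Tests and the acceptance script run the same pipeline at a reduced
budget chosen for a single CPU core: 96×96 rendering canvas (86 px
figure height), 32 px network inputs, CNN widths 8–128 with dropout
0.10/0.25 (the full rates over-regularize a model this small), learning
rate 10⁻³, minimum 12 epochs, patience 8, cap 30.  The synthetic study
uses 10 sequences per class × 60 frames (1,760 SEIs) and averages
held-out accuracy over three seeds.  These sizes are fixed in
`seigait.presets` so results are reproducible at a known cost.

## Known limitations

- The manual video segmentation step is externalized as a manifest
  file; no automatic orientation detection is attempted.
- Decoding MP4/AVI containers requires an imageio ffmpeg plugin;
  without one, ingest accepts PNG frame directories and the rest of the
  pipeline runs from pose files.
- The multi-person rule (largest bounding box = patient) is a
  package decision for frames that include a medical assistant; it is
  untested against real multi-person footage.
- SEI-level splitting can place overlapping windows of one segment in
  both train and test; a subject-level split is the right choice for
  clinical claims and is available by grouping records on
  `subject_id` before splitting.
- ViT-Base is constructible and trainable but impractically slow on
  CPU; the reduced-budget experiments exercise CNN-5 end to end and
  build/forward-check the other six variants.
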