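# seigait

Skeleton-Energy-Image pipeline for video-based grading of Parkinsonian
gait severity.

Parkinson's Disease shows itself early in how a person walks: a stooped,
flexed posture, reduced arm swing, slower cadence and shorter, lower
steps.  `seigait` turns ordinary walking videos — or pre-extracted pose
key points — into compact gait images and trains shallow image
classifiers to grade severity into four UPDRS-derived classes
(*normal / mild / moderate / severe*, gait items 0–3).

## The method

1. **Segment & sample.** Each video is manually segmented (a manifest
   file records the clips and the walking orientation in each) and
   sampled at 10 frames per second.  Segments yielding fewer than 17
   frames are discarded.
2. **Pose estimation & filtering.** A pluggable pose backend returns up
   to 17 COCO-convention joints per person.  Twelve body joints
   (shoulders, elbows, wrists, hips, knees, feet) are kept as triples
   (xᵢ, yᵢ, pᵢ); a joint is valid only when its confidence satisfies
   pᵢ > 0.5, and a frame missing any of the 12 valid joints is dropped.
   Sequences left with fewer than 17 frames are discarded.
3. **Skeleton images (SI).** Each frame's joints are isotropically
   scaled to a vertical extent of 360 px, centered on a 400×400 white
   canvas, and a headless stick figure is traced through a fixed bone
   list with binary dark strokes.  This normalization makes the raster
   invariant to where and how large the subject appeared in the video.
4. **Skeleton Energy Images (SEI).** An SEI is the pixel-wise mean of
   K = 17 consecutive SIs (≈1.5 gait cycles at 10 fps):

       E(i, j) = (1/17) · Σₙ₌₁..₁₇ Sₙ(i, j)

   A rolling kernel over a sequence of N frames produces N − 16 SEIs.
   Gray levels encode dwell time: fast limbs leave light traces, the
   trunk stays near-black.
5. **Datasets & classifiers.** SEIs inherit the video's class label.
   The dataset is split 8:1:1 (train/validation/test) by seeded random
   sampling; a balanced variant duplicates random minority-class images
   until all classes match the majority; a reduced *key-frame* variant
   only keeps windows anchored at frames whose inter-frame difference
   exceeds 1.5× the mean of the preceding 10 differences.  Seven
   classifiers are comparable: CNN-5/6, ResNet-18/34 and ViT
   tiny/small/base, trained from random initialization with AdamW,
   cross-entropy, batch size 64, a 25-epoch minimum and early stopping
   with patience 20 on the validation loss (the retained weights are the
   best-validation checkpoint).

The real clinical videos are not distributable, so the package ships a
parametric **synthetic gait generator**: a sagittal-plane kinematic
chain whose trunk lean, crouch, arm swing, cadence, step length, foot
lift and tremor jitter vary monotonically with severity.  Every stage —
and classifier training — is exercisable end-to-end with no external
data or pose-model weights.

## Worked example

```
seigait simulate --out cohort --sequences-per-class 3 --frames 40 --seed 7
# wrote 12 sequences to cohort
seigait sei --pose-file cohort/poses.csv --out seis --canvas 96 --target-height 86
# wrote 288 SEIs into seis          (12 sequences x (40 - 17 + 1) windows)
seigait dataset --pose-file cohort/poses.csv --out data --seed 7 --canvas 96
# split sizes train/val/test: (230, 29, 29)
seigait train --pose-file cohort/poses.csv --model cnn-5 --seed 7 \
              --min-epochs 20 --patience 10 --out run
```

which prints the held-out evaluation report:

```
overall accuracy: 100.00%  (n=29)
average / weighted-average per-class accuracy: 100.00% / 100.00%
class        prec    rec     f1      acc%    support
normal       1.000   1.000   1.000   100.00       11
mild         1.000   1.000   1.000   100.00        4
moderate     1.000   1.000   1.000   100.00        7
severe       1.000   1.000   1.000   100.00        7
```

The 100% score says the four synthetic severity profiles are cleanly
separable from their SEIs at desk scale — a pipeline sanity check, not a
clinical claim.  `run/` also contains the checkpoint, per-epoch curves
(`curves.csv`) and a provenance record.  The four-experiment protocol
(imbalanced / key-frame / per-class / balanced evaluation) is available
through `seigait experiment --id {1..4}`.

### Pose file dialects

Pose CSV columns: `segment_id, subject_id, label, orientation,
frame_index, joint, x, y, confidence` (one row per key point; joint
names are the 12 body joints, lower-case, or COCO-17 names).  Pose JSON
is one object per sequence with a `frames` array of
`{frame_index, keypoints: [{joint, x, y, confidence}]}`.  Manifest CSV
columns: `video_id, segment_id, start_s, end_s, orientation,
subject_id, label`.  Coordinates are image pixels, origin top-left,
y increasing downward, 0-based.

## Layout

- `seigait.pose` — key-point types, confidence filtering, pose file I/O
- `seigait.ingest` — manifests, frame sampling, short-segment discard
- `seigait.backends` — pose-backend registry (replay / synthetic / yolov8m)
- `seigait.render` — pose normalization and skeleton rasterization
- `seigait.sei` — SEI arithmetic, rolling kernel, key-frame detection
- `seigait.datasets` — records, 8:1:1 splits, oversampling, partitions
- `seigait.classifiers` — the seven model variants and evaluation reports
- `seigait.training` — AdamW training loop with patience early stopping
- `seigait.synthetic` — parametric severity-graded gait generator
- `seigait.nn` — numpy layer framework with explicit backprop
- `seigait.cli` / `seigait.experiments` — command-line surface, experiments 1–4

See `docs/methods.md` for modeling assumptions and numerical choices.
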