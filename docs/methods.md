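# Methods

This note documents the models, rules, and numerical choices behind the
package: what is computed, under which assumptions, and where the design was
genuinely open.

## Problem setting

The package maps raw behavioral video directly to frame-level behavioral
labels, bypassing pose estimation.  A recording is annotated (by a human or
by the rule-based worm classifier below) with discrete behavioral states;
the goal is a model that reproduces those per-frame states on new footage
and emits them as ethograms — per-frame timelines of discrete behavior.

## Label model

Annotations arrive as timestamped bouts (video id, behavior, start s,
end s).  We rasterize them on the frame grid with the convention that frame
`f` represents the instant `f / fps` and bouts are half-open intervals
`[start, end)`; boundary frames are therefore never double-labeled.  In
single-label mode every frame gets exactly one class, with an "other"
background class absorbing uncovered frames; where two bouts overlap, the
bout with the later start wins, ties broken toward the earlier catalog
position (a deterministic stand-in for "most recent behavior"; the
contested frame count is reported as a warning).  In multi-label mode a
frame's target is the set of covering behaviors, and per-entity annotations
(several animals in one scene) are pooled by set union.  Class *names*, not
positions, are authoritative in the JSON interchange schema
(`feral-labels/1`).

## Video handling

Training needs random access to arbitrary frames.  The preprocessing step
standardizes recordings into seekable, lossless, frame-indexable containers
(multipage TIFF, PNG-sequence directories, or uint8 `.npy` stacks) resized
to a fixed square (default 256 x 256) by plain bilinear squash without
aspect-ratio preservation.  Compressed distribution codecs (MP4/AVI/MOV)
must be transcoded externally first; the package detects them and reports
the remediation.  Pixels are stored 8-bit and converted to [0, 1] floats
only at the model boundary; any per-channel standardization belongs to the
encoder plug-in, since pretrained encoders carry their own normalization.

## Chunking

A chunk is `chunk_len` frames (default 64) sampled every `frame_stride`
frames (default 1); consecutive chunks overlap by a fraction of their raw
span (default 0.5, i.e. hop = 32).  The hop is
`max(1, round(chunk_len * stride * (1 - overlap)))`, so "66% overlap" is
realized as an integer hop of one third of the span.  At inference, a final
chunk anchored at `n_frames - span` is appended whenever the regular grid
leaves trailing frames uncovered, so every frame receives a genuine
prediction; training instead skips videos shorter than one span rather than
padding them with fabricated context.  Chunk grids are fixed per epoch
(deterministic) rather than re-drawn with random offsets.

## Model

The encoder is a plug-in behind a small contract: it maps a pixel chunk to
a token sequence `(N_tokens, D)` and exposes an input-to-output ordering of
parameter groups for partial freezing.  The package ships a small trainable
space-time patch transformer (`tiny` backbone: tubelet embedding + learned
positions + pre-LN self-attention blocks) sized to run on one CPU; larger
pretrained encoders register behind the same contract and are never
required by the tests.  No extra transformer layers are inserted between
the encoder and the pooling head — the encoder's own final layers are taken
to provide the token contextualization.

The classification head compresses the token sequence back to the chunk's
temporal resolution: `chunk_len` learnable query embeddings cross-attend to
the tokens (8 heads by default; the head count is unconstrained by the
method and configurable), so query `q` comes to represent sampled frame `q`
purely through the frame-aligned loss — no explicit positional supervision.
The pooled rows are flattened across batch x query, batch-normalized
(batch statistics during training, running statistics at evaluation),
dropped out (p = 0.5), and linearly projected to per-class logits.

All trainable computation runs on a small reverse-mode automatic
differentiation engine over float64 NumPy arrays written for this package;
every primitive's gradient is tested against central finite differences.

## Training regime

* **Loss, single-label** — label-smoothed (0.1) cross-entropy over frames
  with per-class weights proportional to sqrt(1 / class frequency),
  normalized to mean 1.  Square-root inverse frequency amplifies rare
  behaviors without the overcompensation of full inverse-frequency
  weighting.
* **Loss, multi-label** — binary cross-entropy with the positive term of
  class c weighted by `n_negatives_c / n_positives_c`, emphasizing rare
  classes.  Label smoothing is not applied in this mode.  A focal-loss
  modulation exists behind a flag and is off by default (it brought no
  consistent improvement).
* **Augmentation** — one transformation (brightness, contrast, rotation,
  color jitter, or translation) and one strength are sampled per clip and
  applied identically to every frame, preserving temporal coherence.
  MixUp operates at the batch level: partners come from reversing a seeded
  shuffle, one Beta(lambda, lambda) coefficient per sample (default lambda
  0.2, a conventional value; the method does not pin it) applied to pixels
  and element-wise across the temporal dimension to the label rows.
* **Optimization** — Adam with decoupled weight decay 0.1 (skipped for 1-D
  parameters), linear warmup over the first 20% of iterations followed by
  cosine decay to ~0 at the last step, 10 epochs, no early stopping: the
  model trains on the full training set and is evaluated afterward.
  Peak learning rate defaults to 1e-3 for the tiny backbone and 1e-4 for
  pretrained plug-ins (the regime leaves this open; both are configurable).
  Batch size defaults to 4.  NaN losses abort loudly rather than being
  clipped away.
* **Freezing** — the first `ceil(freeze_frac * n_layers)` encoder parameter
  groups (input side) are excluded from updates; `freeze_frac` 0.5 mirrors
  fine-tuning only the upper half of a pretrained encoder.
* **EMA** — an optional exponential moving average of the trainable
  weights, `theta_ema <- 0.999 * theta_ema + 0.001 * theta`, initialized at
  the initial weights.  Reported metrics come from the standard weights;
  the EMA shadow is saved alongside.

## Inference and ensembling

Chunks are predicted in evaluation mode (softmax rows in single-label mode,
sigmoid in multi-label).  Per frame: k >= 1 direct predictions are averaged
arithmetically on probabilities (not logits); stride-skipped frames are
linearly interpolated per class between the two nearest predicted frames;
frames outside the predicted range copy the nearest predicted row (the
two-sided interpolation rule is undefined there).  Averages and convex
interpolations keep simplex rows on the simplex.  Ethograms discretize the
track: argmax with ties toward the lowest class index (single-label) or a
fixed threshold of 0.85 for all classes (multi-label).

## Evaluation protocol

Accuracy is avoided as a headline number because behavioral data are
dominated by the background class.  Reported instead:

* **mAP** — rank-based average precision per class from the continuous
  probability columns, averaged over classes excluding the background.
  Tied scores are resolved analytically as the exact expectation of rank
  AP over a uniformly random ordering of each tie block (conditioned on a
  positive at within-block rank j, the expected number of earlier in-block
  positives is `(j-1)(P-1)/(B-1)`); this is deterministic and
  oracle-checkable.  Calibration means the softmax/sigmoid outputs are used
  as-is.
* **Macro precision / recall / F1** — computed after discretization,
  background excluded; classes never predicted and never true in a split
  are dropped from the macro mean with a warning.
* **Fraction correct** — per-video fraction of frames whose full
  prediction matches (subset accuracy in multi-label mode: one extra
  predicted class makes the frame wrong).
* **Confusion matrix** — single-label only.

## Rule-based C. elegans locomotion classifier

Inputs are per-frame binary masks and centroids from worm tracking, at
6 fps with a required um-per-px scale for the centroid geometry.  The
cascade, first match wins:

1. **turn** — the frame is self-intersecting (outermost contour
   area : perimeter ratio strictly above 3.3), or the posture is sharply
   bent: the midpoint-to-tail vector is longer than the midpoint-to-head
   vector and the angle between them is under 45 degrees.  "Midpoint" is
   the midline point at half arc length.
2. **pause** — |signed speed| < 50 um/s sustained for at least 0.5 s
   (>= 3 consecutive frames at 6 fps), evaluated on maximal sub-threshold
   runs; every frame of a qualifying run is a pause.
3. **forward / reverse** — by the sign of the speed; a zero dot product
   with nonzero speed counts as forward.

Velocity is the centroid difference across 4 frames divided by
dt = 4/6 s = 0.67 s.  Midlines come from skeletonizing non-intersecting
masks and taking the longest geodesic path through the skeleton pixel
graph (which prunes spur branches); they are oriented consistently across
frames by minimizing summed point-to-point distance to the previous
oriented midline, and the head is assigned once per track as the end the
velocity points toward in the majority of frames — a worm that reverses
more than half the time would have the assignment flipped, a documented
property of the rule.  Frames in the initial 4-frame window where velocity
is incomputable are *undefined* unless posture already marks them as turns.

The 3.3 intersection threshold has tracker-calibrated units (pixel
geometry at the original magnification); it is exposed as a parameter, and
contour statistics default to pixel units so the published constant applies
directly.  The 50 um/s speed threshold is physical and requires the
um-per-px scale.

## Synthetic fixtures

The generators define the study conditions for every test:

* **Classification clips** — 32 x 32 px, 10 fps; "other" renders as static
  noise (fixed per-video pattern + per-frame Gaussian noise + slow
  illumination drift), foreground classes as color-coded motion patterns
  (single moving blob; orbiting blob pair; drifting stripe).  Classes are
  separable by construction: a nearest-centroid classifier on per-frame
  channel means exceeds 95% accuracy, which is what makes the end-to-end
  training experiment meaningful.  What passing proves: the full pipeline
  (labels -> chunks -> encoder -> pooling head -> losses -> ensembling ->
  metrics) learns and predicts correctly on cleanly separable data.  What
  it does not prove: performance on real footage, where classes are
  subtler, backgrounds nonstationary, and annotations noisy.
* **Multi-label scenes** — independent entities in image quadrants with
  their own schedules, pooled by union.
* **Worm tracks** — scripted state sequences integrated into centroids at
  6 fps (forward +150 um/s, reverse -150, pause/turn drift 8 um/s — wide
  margins around the 50 um/s threshold); masks are worm-centered 5 px-wide
  tubes (area:perimeter ~ 2.3) that become 12 px discs (~ 6) during turns,
  straddling the 3.3 threshold with stated margins.  Segments shorter than
  the pause-duration rule trigger a warning.

## Worked-experiment scale

The end-to-end experiment (`feral.smoke.run_smoke_experiment`) trains the
tiny encoder (input 32 x 32, 16-frame chunks, embed dim 64, 2 blocks) on
two 192-frame fixture clips for 10 epochs with the full regime and
evaluates on a held-out third clip.  Because the tiny encoder starts from
random weights rather than pretraining, no layers are frozen in this
experiment — freezing buys regularization only when frozen features are
informative; the freezing contract itself is verified separately.  The
full 256 x 256 / 64-frame geometry is exercised in the chunking and video
tests, where it is cheap, rather than in the gradient path.

## Numerical choices and degenerate inputs

* float64 throughout the engine; gradient checks at 1e-7 tolerance.
* Softmax/log-softmax use a constant max-shift (shift-invariance makes the
  gradient exact); log-sigmoid uses the softplus form to avoid overflow.
* Argmax ties go to the lowest class index; AP ties are averaged
  analytically; head/tail assignment ties go to 'first' with a warning.
* Empty event files parse to empty lists; videos shorter than a chunk span
  are skipped (train) or rejected (infer); classes with zero frequency or
  zero positives are hard errors naming the class, since silent drops
  would corrupt the loss weighting.
* Variable-frame-rate input is out of scope: the frame <-> time mapping
  must be affine for label alignment.

## Known limitations

* No pretrained encoder weights ship with the package; the plug-in
  contract is exercised by the tiny backbone only.
* No temporal smoothing/HMM post-filters on ethograms; no bout-level
  (event-based) agreement metrics; no identity tracking.
* The worm classifier assumes a single worm per track and masks good
  enough to skeletonize; detection/segmentation are upstream concerns.
* MP4 decode requires an external transcode step.
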