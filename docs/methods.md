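# Methods

This note documents the models, rules and numerical choices behind the
package, what the synthetic test bed does and does not capture, and the
problem sizes used by the default test suite.

## The scoring problem

An object recognition test (ORT) video shows a rodent in an arena with
one to three objects, filmed from above. The outcome of interest is the
time the animal spends *exploring* each object — classically defined as
frames where the nose is directed at the object within a small radius
(about 2 cm in a real arena) — from which the discrimination index is
computed. The package scores this frame by frame: a supervised
classifier assigns each video frame one class from a user-defined scheme
(background "no object", one class per object, optional whole-body
behaviours such as "stretching" or "on object"), and a stopwatch turns
hard per-frame classes into seconds.

## Frame classifier

A deliberately small VGG-style CNN, trained from scratch per experiment
(there is no meaningful pre-trained model for arbitrary arenas):

- input 150 × 150 × 3, pixel values scaled by 1/255; arena crops of any
  aspect ratio are rescaled to this square (bilinear, aspect not
  preserved);
- four 3 × 3 valid convolutions with 32, 64, 128, 256 filters, each
  followed by 2 × 2 max pooling (spatial sizes 150 → 148 → 74 → 72 → 36 →
  34 → 17 → 15 → 7);
- flatten (7 · 7 · 256 = 12 544), two dense layers of 500 units, dropout
  0.5, and an output head: one sigmoid unit for binary schemes, K softmax
  units otherwise; ReLU elsewhere. 6 912 919 parameters for K = 3.
- Adam, learning rate 1.5e-4, batch size 15, at most 50 epochs; early
  stopping on validation loss with patience 5 and best-weight
  restoration; learning-rate reduction by a factor 0.1 (floor 1e-6)
  after 3 non-improving epochs.

Class imbalance (background dominates every real session) is handled by
inverse-frequency loss weights w_k = N/(K·x_k), which satisfy
Σ_k w_k·x_k = N exactly; the package computes them in rational
arithmetic. With all weights 1 the weighted loss reduces to the plain
cross-entropy (tested identity).

The layers are implemented directly on numpy (BLAS-backed im2col
convolutions with a shift-and-GEMM backward pass). Training streams
uint8 frames and converts one batch at a time to float32, so peak image
memory is O(batch), not O(dataset). Numerical notes: max-pool routes
gradients to the *first* maximum in a window (ties must not duplicate
gradient mass); hard classes break probability ties toward the lowest
class index, so an exactly-uncertain binary frame (p = 0.5) is scored
as background. Fixing the seed fixes initialisation, shuffling and
dropout; bitwise run-to-run determinism additionally requires a
single-threaded BLAS.

## Label and data handling

Labels are interval CSVs (`video_id,start_frame,end_frame,class_name`,
half-open; a seconds dialect maps time t to frame floor(t·fps)). One
class per frame; overlapping intervals with different classes are
rejected. The 80/20 train/validation split is stratified by class with
largest-remainder apportionment (per-class proportions within one frame
of the ratio) and seeded; stratification was chosen over chronological
splitting because frames within a bout are near-duplicates and a
chronological split starves rare classes. The correction loop merges
newly labeled frames over the old set — the newer label wins on
conflict — and retrains from scratch rather than fine-tuning, avoiding
order dependence.

Scoring-video assembly: n representative videos are chosen by k-means
(k = n) over appearance features — the temporal-mean frame, grayscale,
block-averaged to 16 × 16 — with one seeded random pick per cluster;
from each minute of each selected video one contiguous fragment of
round(j/(i·n) · 60 · fps) frames is cut (j < i·n enforced). Fragments
start at minute boundaries by default (an option gives seeded offsets
within the minute); totals can differ from j minutes by under one frame
per segment due to rounding. An index map records merged-frame → source
frame exactly, so labels placed on the scoring video land back on the
intended source frames.

## Stopwatch and discrimination index

seconds(c) = (#frames classified c)/fps, totalled and per 1-minute
segment (the last segment may be short); all time accounting is exact
rational arithmetic, so class seconds always sum to the video duration.
The DI is DI_acq = t_o1′/(t_o1+t_o1′)·100 and
DI_test = t_o1/(t_o1+t_o2)·100; which classes play the familiar/novel
roles is project configuration, never inferred. Zero combined time
raises an undefined-DI error (the animal would be excluded); no minimum
exploration-time exclusion threshold is hard-coded. An optional odd-width
median filter over hard classes (default off) removes 1–3-frame
prediction flips, which are mostly borderline frames; exploration time
otherwise counts raw hard-classified frames.

## Evaluation

Weighted F1/recall/precision are computed closed-form from the confusion
matrix with weights proportional to true-class support; zero
denominators contribute 0 and zero-support classes carry no weight.
Method-to-rater agreement is the Spearman rank correlation of
per-1-minute-segment, per-object scores (average ranks on ties; pooled
across objects by default, per-object optionally; undefined on constant
input). Misclassified frames are grouped into maximal runs homogeneous
in their (true, predicted) pair — six possible pairs for three classes;
run lengths sum exactly to the off-diagonal confusion count. The
run-length analysis Spearman-correlates per-video accuracy with the
per-video count of runs of each pair at each length 0–50 (exact-length
counting by default, at-least-length behind a flag; cells with constant
counts across videos are undefined and reported missing). The
time-saved model assumes scoring effort proportional to footage:
labeling f frames of footage costs (f/(fps·60))·(scoring rate) minutes,
compared against scoring all n videos.

## Synthetic arena generator

The generator is the package's test bed: a rectangular or circular
arena, static circular objects, and one agent rendered as a flat-shaded
ellipse (length 24 px) with a small nose marker that makes heading
visible to the classifier, over a uniform background with Gaussian pixel
noise (σ = 2 intensity units). Kinematics are a correlated random walk
with finite-state dwell modes (roam → approach → explore → on-object /
stretch), reflecting walls, object attraction probability 0.3 at roam
expiry and exploration bouts of 10–60 frames. Defaults were chosen once
so that 15–30 % of session frames are exploration — a realistic minority
— and both short (≤ 3 frame) and long bouts occur.

Per-frame ground truth is *derived from the same kinematic state that
rendered the frame* by the scoring rule: class k iff the nose point is
within the exploration radius (default 8 px, the pixel-space analogue of
the 2 cm rule; there is no camera calibration) of object k's boundary
and the heading lies within ±90° of the bearing to the object centre;
"on object" iff the body centre is inside the object disc (a class when
enabled, excluded otherwise); "stretching" is tied to the stretch dwell
mode. Labels are therefore exactly re-derivable from the stored
trajectories. Contrast regimes emulate pale-on-pale ("bright") and
dark-on-dark ("dark") recordings, with agent/background mean-intensity
gaps within a 20-unit low-contrast bound; "normal" exceeds it.

What the generator does **not** emulate: fur texture, posture change,
shadows, lens distortion, reflections, occlusion or multi-animal scenes.
Passing tests on synthetic data show the pipeline's machinery is
correct end to end and that the classifier can learn the scoring rule
from pixels; they do not certify accuracy on real recordings.

## Problem sizes in the default suite

The end-to-end check trains on a seeded synthetic experiment of 3 videos
× 2 min at 25 fps (9 000 frames), normal contrast, 3 classes, with
exactly 3 000 frames labeled through a sampling plan (n = 3, i = 2,
j = 2, fraction 1/3); training runs 5 epochs — the package's
reduced-epoch setting for desk-scale runs, chosen with the single-CPU
budget in mind — and is checked for held-out weighted F1 ≥ 0.90 on the
6 000 unlabeled frames and for recovery of each object's total
exploration time over the experiment within 5 % of ground truth. The
5 % bound is asserted on per-object totals across the experiment's
videos (the cohort-level quantity the method is used for);
per-(video, object) errors are intrinsically larger at this scale — a
single mis-scored bout boundary on an 11-second-exploration video
already exceeds 5 % — and are reported, not gated. At this reduced
epoch budget the time-recovery bound is the binding constraint: the
residual exploration-time bias shrinks with further training epochs,
which the desk-scale CPU budget does not accommodate.
Unit tests of training mechanics use a shrunken
configuration (14 × 14 input, 4/8 filters, 16-unit dense) because the
callback logic is size-independent. Video files in tests are small
uncompressed AVIs generated on the fly.

## Known limitations

- The AVI layer supports exactly one flavour (uncompressed 24-bit,
  single video stream) — by design, for lossless round trips without a
  codec dependency.
- Training on a single CPU is minutes, not seconds; real-scale
  experiments (10⁵ frames, 50 epochs) want a GPU-backed reimplementation
  of the same specification.
- The intensity-based quadrant rule assumes a single animal and a
  reasonably static background; it reports "not located" rather than
  guessing when no quadrant deviates above the noise floor.
- Spearman agreement is undefined for sessions with constant segment
  scores (e.g. an animal that never explores); such sessions surface as
  errors/missing values, not silent zeros.
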