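# Methods

This note records the models, the synthetic study conditions, the numerical
choices and the known limitations of the `ageaug` pipeline, in the order the
pipeline runs.

## Backbone and numerical core

The backbone is a standard pre-norm vision transformer over square grayscale
images: non-overlapping patches (row-major, top-left to bottom-right) are
linearly embedded, a learnable CLS token is prepended, learnable position
embeddings are added, and the sequence passes through `depth` blocks of
multi-head self-attention and a GELU MLP, ending in a final layer norm. The
desk-scale default is image 32, patch 8, 6 heads, 2 blocks, embedding 48 —
small enough that a forward+backward step on a batch of 8 takes ~15 ms on
one CPU, while keeping the six-head semantics of the reference scale
(224×224, patch 16, ViT-S).

No deep-learning framework is used; the networks run on an in-repo
reverse-mode autodiff core (`ageaug._autodiff`) over float64 NumPy. This
keeps every training trajectory bit-reproducible from its seeds on a single
CPU thread, which the reproducibility contracts (identical seeded runs,
byte-identical experiment reports) rely on.

Initialization: projection weights are Xavier-scaled (`1/sqrt(fan_in)`), but
the query/key columns are further scaled by 0.1 so that initial attention is
near-uniform, as in standard large-ViT initialization. Two reasons. First,
full-scale Q/K init produces arbitrarily structured initial attention whose
entropy sits *below* the self-distillation training equilibrium, so
pretraining would *raise* attention entropy; from near-uniform attention the
training demonstrably sharpens it. Second, Xavier-scale value/MLP paths keep
the token features input-sensitive (~0.1 feature s.d. across images), which
random fine-tuning at n≈60 needs; the original 0.02-everywhere convention
left features with ~1e-4 input sensitivity and untrainable heads.

The classification head reads the CLS feature concatenated with the mean
patch-token feature. With near-uniform attention the CLS token alone is a
poor bottleneck at this scale; the pooled half keeps local lesion structure
visible to the linear head. Conventional alternatives (pure CLS readout,
softmax cross-entropy) remain available behind flags.

## Self-distillation pretraining

Teacher and student share the ViT architecture plus a 3-layer projection
head (hidden 64, output 64 at toy scale). Each step: every image yields two
global crops (target 32 px, area fraction 0.5–1.0) and four local crops
(target 16 px, area 0.1–0.4), square, lightly augmented by horizontal flip
(p = 0.5) and Gaussian blur (p = 0.5, σ ∈ [0.1, 1]); photometric color
operations are omitted for single-channel phantoms. The student sees all
crops, the teacher only global crops; every (teacher global g, student crop
c ≠ g) pair contributes a cross-entropy term between the teacher's
centered, sharpened softmax (temperature 0.04) and the student's softmax
(temperature 0.1). The teacher is an EMA of the student; the centering
vector is an EMA (momentum 0.9) of the teacher's batch-mean output. The
teacher checkpoint with the lowest per-epoch mean loss is kept.

Desk-scale optimizer choices, fixed once after measuring trainability at
the study conditions (32 phantoms, batch 8, 20 epochs = 80 steps): Adam at
lr 5e-3 and teacher momentum 0.9. Smaller rates (1e-4) leave the loss flat
and attention uniform within this budget; production-scale schedules
(lr ~1e-4, momentum 0.996+) assume thousands of steps. With these settings
the distillation loss falls and the teacher's mean CLS-attention entropy
drops below its initialization in 10/10 seeds on ROI-only-variation
phantoms. Local crops are handled by bilinear resampling of the patch
position embeddings. Smaller entropy drops (~1e-3 nats) are typical —
attention sharpens only mildly in 80 steps.

## Masks and erasing

A head's CLS→patch attention (CLS→CLS weight dropped, renormalized) is
thresholded at patch resolution and upsampled by nearest neighbour (bilinear
would produce non-binary masks). Threshold strategies: `mass_fraction`
(default 0.6 — smallest set of top cells holding 60 % of attention mass,
ties broken row-major; scale-free across heads), `quantile`, and `absolute`.
Erasing overwrites non-retained pixels with a constant fill (default 0,
matching the near-black mammographic background; configurable, e.g. to a
dataset mean). The Bernoulli draw is per image per epoch; the mask itself is
computed once per image from the frozen teacher and cached, so training is
deterministic given seeds. Random erasing follows the standard recipe: one
rectangle, area fraction in (0.02, 0.4), aspect ratio in (0.3, 1/0.3),
per-pixel random fill, resampled until the post-rounding geometry satisfies
the configured bounds (up to 100 tries, then identity with a warning).

## Transfer learning, head selection, sweeps

Fine-tuning updates all parameters plus the new linear head with Adam
(reference protocol: lr 5e-6, weight decay 1e-4, batch 8, up to 100 epochs,
five repetitions; desk-scale runs use lr 1e-4, up to 60 epochs), one-vs-all
sigmoid outputs with summed binary cross-entropy, and a global gradient-norm
clip of 1.0 for stability. Early stopping monitors validation macro F1
(patience 10); the best-validation-epoch model is evaluated on the test
split. Augmentations touch training images only; validation/test batches
are bit-identical across arms.

Head selection trains once per head with erasing restricted to that head
under a shared seed and keeps the arg-max validation F1 (ties → lowest
index). Because per-head full fine-tuning at n≈60 is dominated by run
noise, the selection runs use a *screening mode*: the backbone is frozen and
only the linear head is trained, full-batch, to convergence (lr 1e-2,
weight decay 0.01 ≈ the regularization of a standard logistic probe).
Features are cached per (image, erased/clean) state, making the six
screening runs take ~2 s. The probability sweep follows the same pattern
over P ∈ {0.2, 0.4, 0.6, 0.8}. The final three-condition comparison uses
full fine-tuning.

The "fewer than 50 pixels" dense-tissue heuristic is exposed as a predicate
on mask cell counts. The reference description counts pixels on the 14×14
patch grid reading; whether the count is taken at patch or pixel resolution
is configurable because either reading is defensible — the caller chooses
the mask resolution.

## Statistics

Macro F1 averages per-class F1 over *all* classes, scoring 0 for a class
with a zero precision+recall denominator. Conditions are summarized as
mean ± sample s.d. (n−1) over repeats and compared with Student's pooled
two-sample two-tailed t-test (Welch's variant behind a flag; the pooled
form is the common reading of an "unpaired t-test"). Degenerate
zero-variance inputs return (t = 0, p = 1) for equal means and a
minimal-positive p otherwise. Markers: `*` for p < 0.0001, `+` for
p < 0.05, the AGE table row showing the weaker of its two comparisons.

## Synthetic phantoms

All tests run on 32×32 phantoms with ground-truth ROI masks:

* **density** (4 ordinal classes): a half-ellipse breast on dark background;
  dense-tissue area fraction drawn from disjoint per-class bands
  (4–8 %, 13–19 %, 26–36 %, 48–60 % of the foreground), so the ordering is
  strict for every seed.
* **malignancy** (3 classes): a dense disk ROI inside the breast containing
  2–10 bright lesion spots whose count band encodes the class.
* **calcification_patch** (3 classes): a micro-calcification cluster whose
  spot count (2–3 / 6–8 / 12–15) and cluster radius (2–3 / 3.5–4.5 / 5–6 px)
  encode the class; this area-plus-count cue is the substrate for the head
  selection and condition-comparison experiments.
* **mass_patch** (3 classes): a central blob whose boundary irregularity
  (sinusoidal perturbation amplitude/frequency) encodes the class.

Background distractors are 2–4 bright decoy spots with label-independent
count and brightness drawn over the whole lesion range: a classifier
reading spot statistics off the full image absorbs their noise, which is
exactly what attention-guided erasing removes during training. Classifier
probes confirm the construction: simple ROI pixel statistics separate the
calcification classes at macro F1 = 1.0, while the same statistics on
background pixels sit within 0.02 of chance.

A fixture attention provider plants one head whose attention places
≥ `alignment` of its mass on ROI-overlapping cells (proportional to
overlap) with the remainder uniform; other heads draw near-uniform gamma
noise (shape 25). This enables head-selection tests with no pretraining.

## What the phantoms do and do not show

Passing tests show the *mechanics* are correct — masks, erasure semantics,
selection logic, statistics, reproducibility — and that the study-condition
comparisons behave sensibly (erasing-style augmentation does not hurt, and
modestly helps, small-sample training). They do not show that AGE's
clinical-scale benefits reproduce: those rest on a strong pretrained
representation (ImageNet + large-scale self-distillation) in which an
aligned attention head reliably marks diagnostic tissue. At desk scale,
with a randomly initialized toy backbone and 60 training images, the
recovery of a planted ROI-aligned head by validation F1 is *not* reliable:
macro F1 on a 20-image validation split is granular (s.d. ≈ 0.07),
best-epoch selection favors noisy runs, and random occlusion by misaligned
masks acts as a benign regularizer rather than a penalty, so the aligned
head's average advantage (≈ +0.05–0.1 F1) is smaller than the spread of the
maximum over five noise heads. The dedicated selection test states the
intended 9/10-seed recovery property and currently fails it; this is a
scale limitation of the phantom system, not of the selection logic, which
is exercised separately with scripted run outcomes.

## Problem sizes and runtime

Defaults used by the tests and the acceptance script: 32 pretraining
phantoms for 20 epochs (~5 s per seed), 60/21/18 train/val/test splits for
selection and comparison experiments, screening in ~2 s per six-head
selection, full fine-tuning arms in ~1–3 s per run. The complete test suite
runs in about two minutes, the acceptance script in about one, on a single
CPU.
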