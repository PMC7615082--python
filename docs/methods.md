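# Methods

## Problem setting

The package models five-year incident-disease risk from long, multimodal
primary-care histories. Each patient is a date-ordered sequence of records
from nine modalities: diagnoses, medications, procedures, tests, systolic
and diastolic blood pressure, BMI, smoking status and drinking status.
Vanilla Transformer encoders truncate such sequences (typically to 256
records), discarding the early history; the hierarchical encoder here is
designed to keep the whole learning period in view at sub-quadratic
attention cost.

## Cohort construction

For a target condition defined by a code set, the incident date is the
first occurrence of any defining code (or the entry in an outcomes table,
whichever is earlier). Cases receive a baseline date drawn uniformly from
the window one to five years before the incident; controls receive a
baseline drawn uniformly subject to at least five years of follow-up.
Patients with under three years of history before baseline are excluded.
The label is 1 when the incident falls in (baseline + 1y, baseline + 5y];
an incident inside the first blanked year, or follow-up ending before
baseline + 5y, excludes the patient; otherwise the label is 0.

All date arithmetic uses a 365.25-day year, with multi-year windows rounded
to whole days (1y → 365, 3y → 1096, 5y → 1826). This single rounding
convention makes the baseline-sampling windows and the labelling windows
agree exactly at their boundaries (a case sampled at the edge of its
window is never re-classified as blanked).

## Sequence encoding

Continuous measurements are discretized into fixed-width bins over
plausibility ranges — systolic 80–200 mmHg and diastolic 50–140 mmHg in
5-mmHg steps, BMI 16–50 kg/m² in 1-unit steps; readings outside the range
are dropped. Bins are half-open with the top boundary closed, so a
boundary reading (e.g. exactly 200 mmHg) is kept rather than silently
discarded. Note the diastolic scheme yields 18 bins by the formula
(140 − 50)/5; a data-driven count over observed values can be smaller.

Records sharing a calendar date form one visit (the only grouping key
available in long-format extracts). Each encoded record carries four ids:
token, age in whole years at the event (clamped to 0–110), a visit-parity
segment id alternating 0/1, and a per-visit position id. Sequences longer
than the model's maximum length keep the most recent records; the
pre-truncation count is retained as the patient's EHR length for subgroup
analyses. Padding is on the right and masked out of every attention
computation. Ties within a date keep input-file order (stable sort).

## Model

Both models embed a record as the sum of token, age, segment and position
embeddings. The **flat baseline** is a post-layer-norm BERT-style encoder
(defaults: hidden 150, 6 heads, intermediate 108, 8 layers, maximum length
256) with a CLS token prepended; risk is predicted from a tanh-pooled
affine of the first position.

The **hierarchical model** slides a window of 50 records with stride 30
over the encoded sequence (maximum length 1220 by default, i.e. 40
windows). A shared-weight *local feature extractor* Transformer (4 layers)
encodes each window independently; one vector per window is pooled (first
position by default; mean over real positions as an alternative — see
below). A *feature aggregator* Transformer (4 layers) with its own learned
position embeddings and a learned CLS vector summarizes the window
representations; risk is predicted from the tanh-pooled CLS state. The
largest attention matrix side is therefore max(window, number of windows),
50 at the default geometry, versus 256 for the flat model.

Windowing guarantees full coverage: stride-aligned starts, plus one extra
window anchored at n − W whenever the last aligned window stops short of
the end. At the default geometry the full-coverage count for length 1220
is 40 (the last window is exactly (1170, 1220)). When a configured maximum
length equals W + k·S the grid tiles it exactly, and padding a sequence
further only adds fully-masked windows — the practical reason the shipped
profiles use such lengths (1220, 440, 380, 140).

Weight initialization is truncated normal (σ = 0.02, clipped at 2σ), fully
seeded. Dropout defaults follow the full-scale setting (0.2 hidden, 0.3
attention); the CPU test profile disables dropout since its few-epoch runs
operate in an underfitting regime.

## Self-supervised pre-training

Pre-training follows the bootstrap-your-own-latent pattern adapted to
sequences: an online network (encoder, per-timestep projector and
predictor, each a one-hidden-layer MLP) is trained to match an EMA target
network (encoder + projector, decay τ = 0.996, no gradients). The scheme
is single-sided: only the online path is augmented.

Augmentation has two levels. *Sequence level:* with probability 0.5 the
history is cropped to a uniformly chosen contiguous visit interval, then
each token is replaced by MASK with probability 0.2. The crop is applied
to both paths so that the window grids — and hence the per-timestep loss —
stay positionally aligned; token masking is online-only. This shared-crop
reading is an interpretive choice: the per-timestep similarity objective
is ill-defined if the two paths window different spans. *Segment level:*
each real window representation independently joins the augmented set with
probability 0.5 (a per-sequence variant is available in the config), and
members are zeroed with probability 0.85 or perturbed with standard
Gaussian noise with probability 0.15.

The loss at each augmented timestep is the squared Euclidean distance
between L2-normalized online prediction and target projection, equal to
2 − 2·cos θ and bounded by [0, 4]; timestep losses are summed per example
and averaged over examples with a non-empty augmented set. Pre-training
uses SGD with momentum 0.9 and a warmup + cosine-decay schedule.

One-sided self-distillation objectives collapse easily at small scale, so
three standard safeguards are built in: the projector/predictor hidden
layers are layer-normalized, the predictor can be trained faster than the
encoder (`predictor_lr_scale`, default 10), and weight decay is
configurable. The EMA decay must also be read relative to the step
budget: τ = 0.996 (the full-scale default) corresponds to a ~250-step
memory, appropriate for hundreds of thousands of steps but far too short
for a few hundred — the desk-scale benchmark therefore uses τ = 0.9998,
keeping the target close to its initialization over its ~800-step run.
Even so, loss going to zero with a drifting target indicates collapse;
the pre-training log's representation statistics should be checked.

## Optimization and evaluation

Supervised training uses Adam with a three-stage schedule — linear warm-up
over the first 10% of steps, constant peak (default choices 5e-5, 1e-4,
5e-4 at full scale), cosine decay to zero over the last 50% — batch size
128, and early stopping when the strict running-minimum validation loss is
more than 6 epochs old. The best-validation-loss weights are restored.

Metrics are AUROC (Mann–Whitney form) and AUPRC (step-interpolated,
average-precision form), computed through scikit-learn and verified in the
test suite against brute-force pairwise and all-threshold oracles.

Three protocols mirror the full-scale analyses: (i) length-subgroup
evaluation at a 256-record threshold, including a positive-rate-matched
long subgroup (all negatives kept, positives subsampled without
replacement to the short subgroup's prevalence, averaged over 5 draws);
(ii) learning curves over training-set fractions {1, 5, 10, 20, 50, 100}%
averaged over 3 seeds, with an optional pre-trained arm (subsampling is
without replacement — resampling with replacement would distort prevalence
at the 1% end); (iii) modality ablation adding one modality at a time to a
diagnosis + medication base, with records of excluded modalities dropped
before encoding.

## Synthetic cohorts

No suitable public corpus of multi-decade, multimodal primary-care
sequences exists, so every quantitative claim is exercised on simulated
cohorts with known ground truth. Visits arrive as a gamma renewal process
(shape 2), giving overdispersed gaps and a long right tail of sequence
lengths; each visit carries a Poisson(4) number of records with a
realistic modality mix; continuous modalities draw clipped-normal values
inside their binning ranges. Outcome risk is logistic in a binary carrier
flag: carriers (20% of patients) receive a set of recurring marker codes
(default 20 insertions from a 4-code set) and have ~50% five-year risk
versus ~2% for non-carriers (β₀ = −3.9, β₁ = 3.9, ~10% prevalence). Marker
depth is controllable: *recent* places markers among the newest records;
*deep* places them strictly older than the newest 256 records, so a
256-truncating model provably cannot see them. Under the deep setting the
generator enforces a minimum record count (regenerating the patient's
timeline draw when below it) so that planting depth is always feasible.

Codes are drawn i.i.d. within a modality by default. Optional
latent-phenotype mixing (`n_phenotypes`, `phenotype_weight`) gives each
patient a topic that biases code choice toward a phenotype-specific
sub-vocabulary, emulating comorbidity-style code co-occurrence; with
`signal_phenotype`, carriers additionally draw from a carrier-linked
sub-vocabulary throughout their history. The transfer cohort enables
this (without co-occurrence, the content of a masked record is
statistically independent of its context, and a masked-prediction
pre-training objective has nothing to learn); the deep-signal cohort
keeps codes i.i.d. so its long-range contrast isolates receptive field.
The generator still does not emulate temporal disease progression or
informative visit timing; passing the benchmarks demonstrates
architectural and pipeline properties, not clinical performance.

The benchmark cohorts use generator-assigned baselines when building model
examples, which keeps each planted marker's depth relative to the
newest-256 boundary exact; the stochastic baseline-selection pipeline is
validated separately against the generator's ground truth.

## Desk-scale benchmark choices

The shipped benchmarks must run on one CPU in minutes, on a numpy
backend written for this package (no GPU framework is used). The choices
below are scale adaptations, not changes of substance:

* **Test profile**: hidden 32, 2 heads, intermediate 64, 1 + 1 layers
  (hierarchical) / 2 layers (flat), window 50 / stride 30 retained,
  maximum length 380–440; dropout off.
* **Window pooling**: the test profile pools windows by masked mean rather
  than first position. At this capacity and step budget, first-position
  pooling leaves the marker's influence on a window representation almost
  entirely inside the attention value path, which adapts too slowly for
  desk-scale budgets; mean pooling places it directly in the
  representation. The full-size default remains first-position pooling.
* **Optimizer**: Adam(0.9, 0.98) at peak 3e-3, batch 16. The imbalanced
  objective has a long base-rate plateau before the marker direction is
  found; the faster second moment roughly halves the plateau at this
  scale. Benchmarks disable early stopping because the plateau would
  otherwise trigger it just before escape.
* **Problem sizes**: long-range benchmark 800 train / 250 validation
  patients (~380 records each), hierarchical 11 epochs, flat baseline 6
  epochs (its validation loss converges within 2–3 epochs since the
  planted signal is outside its receptive field); transfer benchmark
  8000 train / 2000 validation short-sequence patients, 800 BYOL steps,
  1% label subsets (80 examples), 40 fine-tuning epochs with
  best-tune-loss restoration; 3 seeds throughout.

## Numerical notes

All floating-point work is float32. Attention masking adds −1e9 to masked
scores; the softmax implementation clips shifted logits at −50 before
exponentiation (masked weights ≈ 1e-22, avoiding denormal-heavy `exp`).
Fully-padded windows would make a softmax row degenerate, so they receive
a dummy all-ones key mask and their representations are zeroed and masked
out of the aggregator. L2 normalization in the BYOL loss raises on
zero-norm inputs rather than adding an epsilon. The per-visit position id
table is sized to the maximum length plus one and ids are clamped;
age ids are clamped to 0–110.

## Known limitations

* The numpy backend is single-threaded BLAS-bound; full-size (hidden 150,
  4 + 4 layers, length 1220) training is supported but slow, and the
  shipped experiments use the test profile.
* The flat baseline rebases visit positions after truncation; ages are
  kept absolute.
* Fine-tuning on a handful of examples (the 1% subsets) is high-variance;
  the transfer benchmark reports 3-seed means, and single-seed results
  can deviate substantially.
* The simulator's independence assumptions (codes i.i.d. within a
  modality unless phenotype mixing is enabled, markers placed uniformly
  in depth) make the planted signal easier to detect than a comparable
  clinical signal would be.
* At desk scale the BYOL pre-training, while mechanically correct
  (verified loss algebra, EMA coupling, gradient isolation) and capable
  of improving full-label linear-probe quality with long gentle runs,
  has not been observed to improve few-label fine-tuning over training
  from scratch: the transfer benchmark reports both arms and, in our
  runs, the from-scratch arm is at least as good. The full-scale method
  pre-trained on millions of patients for orders of magnitude more
  steps; closing this gap at desk scale is an open problem for the
  package.
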