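# Methods

## Problem and model

The package classifies paired 8-second single-lead ECG and heart-sound
(PCG) windows as normal or abnormal. Each modality is encoded by a
convolutional branch into a fixed-size embedding; the bimodal classifier
concatenates the two embeddings and applies a small MLP with a sigmoid
output (late fusion). The abnormal class is positive throughout; the
decision threshold is fixed at 0.5 (no threshold tuning is performed
anywhere).

### 1D-CNN branches

A branch is a stack of blocks — 1D convolution (stride 1, "same"
padding), batch normalization, ReLU, and a non-overlapping pool of size 2
— followed by global average pooling over time and a dense head
(embedding → 64 → ReLU → dropout → 1). Four canonical configurations are
provided (depths 5–8 with feature maps growing 16→256 and kernel sizes
decreasing 7→3), each crossed with three pooling modes (`all_avg`,
`all_max`, and `both`, where the first ⌊n/2⌋+1 blocks pool by averaging
and the rest by max) and dropout ∈ {0, 0.2} — 24 variants.

With halving pools, block *b* with kernel *k* adds *k*·2^*b* input samples
to the receptive field: RF = 1 + Σ_b k_b 2^b, i.e. 110 / 226 / 418 / 834
samples for depths 5/6/7/8. At the default ECG rate of 500 Hz only the
depth-8 stack spans a full 1 s average heartbeat; `check_receptive_field`
warns (never errors) when a configuration falls short. The formula is
verified in the tests against a gradient-span oracle (the span of input
positions with non-zero gradient for one interior output).

### Audio-style PCG backbone

For transfer learning the PCG branch can instead be a 2D CNN over log-mel
spectrograms: a fixed front-end (Hann-windowed frames, power spectrum,
Slaney-normalized triangular mel filterbank, log compression; defaults
FFT 256, hop 80, 64 mel bins at 1 kHz) followed by six double-conv blocks
with channel doubling (base 64 → 2048-dim embedding) and a fresh MLP head.
The first *k* blocks can be frozen; pretrained backbone weights can be
loaded from `.npz` (the replaced head never is; shape mismatches outside
the head raise with the offending tensor names; absent weights fall back
to random initialization with a logged warning). The two-stage transfer
schedule fine-tunes first on pooled unimodal heart-sound corpora with 0–3
blocks frozen, then on the downstream bimodal data with 4 or 5 blocks
frozen.

### Numerical engine

No deep-learning framework is used: `cardiofuse._nn` implements the
layers with manual backpropagation in numpy, using a channels-last layout
so convolutions run as shift-and-add batched GEMMs. Parameters are
float32 (float64 on request, used by the finite-difference oracle tests);
He initialization; Adam with optional decoupled (AdamW-style) weight
decay applied to weight matrices only. All gradients are verified against
central finite differences in the test suite. Frozen layers keep
receiving gradients (so earlier layers could still train) but are skipped
by the optimizer, which makes "frozen weights are bit-identical after
training" an exact contract.

## Training protocol

Binary cross-entropy on logits, Adam (default learning rate 1e-3, batch
32 — the experiment protocols use 2e-3/64 for speed), early stopping on
validation accuracy with patience 15: training stops after `patience`
consecutive epochs without strict improvement, and the weights of the
best epoch are restored. Among epochs that *tie* the best monitor the
checkpoint keeps the **latest** weights: on strongly separable synthetic
cohorts validation accuracy saturates within an epoch, and restoring the
first tying epoch would return a nearly untrained fusion head, which
distorts gradient-based attribution. The patience counter itself still
counts only strict improvements, so the stopping epoch is unchanged.

The fusion head in the experiment protocols is trained to a fixed budget
(300 epochs, learning rate 5e-3, weight decay 0.1) for the same reason:
its monitor saturates immediately, and a converged, regularized head is
what makes the head's gradients reflect which modality it actually uses.
When both branches are frozen (the default), the head trains on cached
branch embeddings, which is orders of magnitude faster than
backpropagating through the branches.

Model selection in `grid_search` ranks candidates on the validation
split by default; ranking on the test split — a protocol some studies
report — is only honored behind an explicit `replicate_paper_selection`
flag with a logged leakage warning.

## Synthetic cohorts

The generator emulates the data regime of an augmented bimodal
heart-sound corpus: paired 8 s windows, one cardiac rhythm per record
shared by both modalities, binary labels, several records per patient.

* **ECG**: per cycle, five Gaussian deflections (P, Q, R, S, T) with
  offsets scaled to the cycle length, 2% SD cycle-length jitter, 0.3 Hz
  baseline wander, additive Gaussian noise (default SD 0.05 against an R
  amplitude of 1). Pathology = ST-segment elevation (0.18·effect), PR
  prolongation (40 ms·effect) and T-wave flattening.
* **PCG**: per cycle an S1 burst (decaying sinusoid, 50–150 Hz band) at
  cycle start and an S2 burst at 35% of the cycle; pathology = a
  band-limited (100–400 Hz) noise murmur gated to systole with amplitude
  0.5·effect.
* Abnormal patients draw their evidence channel (`ecg_only`, `pcg_only`,
  `both`) from the cohort's `modality_evidence` distribution, which lets
  tests place the class signal in exactly one modality.

Defaults: 500 Hz ECG, 1 kHz PCG, heart rate 55–95 bpm, effect size 1,
noise SD 0.05. Signals are z-scored per recording. What the generator
does **not** emulate: realistic ECG morphology beyond the Gaussian model,
respiratory modulation, sensor artifacts, multi-lead recordings, or the
heterogeneity of real pathology — so passing tests demonstrate that the
pipeline's machinery is correct and that its claims hold under controlled
evidence placement, not that real-data performance is reproduced.

## Evaluation statistics

AUROC is the Mann–Whitney pair statistic computed via midranks (exactly
(concordant + ½·tied)/(n₊·n₋); verified against an O(n²) oracle at 1e-12).
Bootstrap CIs are percentile intervals over 100 sample-level resamples
(resamples missing a class are redrawn); patient-level resampling is
deliberately not the default, as the minimal reading of "bootstrap
resampling", and is noted as a limitation. DeLong's test uses midrank
placement values with the standard variance/covariance estimator; the
degenerate zero-variance case with equal AUCs returns p = 1. The Wilcoxon
signed-rank test drops zero differences, enumerates all 2ⁿ sign
assignments for n ≤ 12 (two-sided p as the probability of a deviation
from the null mean at least as large as observed; valid under ties), and
otherwise uses the normal approximation with tie and continuity
correction.

## Explainability

All gradient attributions target the abnormal-class logit (pre-sigmoid)
to avoid saturation. Grad-CAM weights the final conv layer's channels by
their time-averaged gradients, applies ReLU, and upsamples linearly to
signal length. Multi-Layer Grad-CAM builds one map per last-three conv
layers with absolute time-averaged-gradient channel weights and fuses
them convexly; the fusion weight of a layer is the absolute Pearson
correlation of its upsampled map with the **absolute value of the raw
input** (an envelope proxy — raw signed signals correlate poorly with
non-negative maps by construction; this reference choice is an
interpretation of "correlation with the input sample"). Constant maps get
weight 0; all-constant layer sets are flagged degenerate.

LIME cuts each modality into 16 equal segments (0.5 s at 8 s), masks a
uniformly random half of all 32 joint segments per perturbation,
replacing masked samples by Gaussian noise with the segment's own mean
and SD, and fits a ridge surrogate from mask vectors to model probability
with proximity weights exp(−d²/0.25²), d = cosine distance of the mask to
all-ones. Note two structural properties of this perturbation: it
preserves a segment's moments (so only *temporal structure* is
destroyed — a model reading a segment's mean is invisible to it), and
the injected noise itself resembles a broadband murmur, which dampens
LIME's contrast on murmur-driven PCG classifiers. Both effects are
inherent to distribution-matched noise perturbations and are documented
rather than patched.

The modality-contribution metric normalizes a sample's ECG and PCG
heatmaps by their **joint** maximum (the only scope making the two means
comparable within a sample; LIME maps use |coefficient| expanded to
sample resolution) and reports each modality's mean; per (method, class),
contributions are compared across samples with the paired Wilcoxon test
and the conventional star banding (5e-2 / 1e-2 / 1e-3 / 1e-4).

## Embedding visualization

Fusion embeddings are projected with UMAP (defaults n_neighbors 15,
min_dist 0.1, mandatory seed) and class separation is scored by the mean
Euclidean silhouette; identical points return 0 with a degeneracy flag.
Subclass annotations (when present) are used for coloring only, never for
training.

## Experiment protocols and problem sizes

`cardiofuse.experiments` fixes the three reproduction analyses: fusion
benefit (300 patients per cohort, abnormal evidence half ECG-only / half
PCG-only, three seeds, depth-5 branches), modality shift (100 patients,
PCG-only evidence, contributions of abnormal test windows, LIME with 300
perturbations), and embedding separation (60 patients, three seeds, a
small 3-block branch). These sizes were chosen so each analysis completes
in minutes on a single CPU while leaving comfortable statistical margins;
they are the package's study conditions, not tuned values.

## Known limitations

* The numpy engine is CPU-only and single-threaded-BLAS-friendly; it is
  not intended for large-scale training.
* Bootstrap CIs resample windows, not patients; with several windows per
  patient the intervals are anti-conservative.
* The synthetic murmur is stationary band-noise; real murmurs have
  pitch/shape structure the generator ignores.
* Published parameter counts for the canonical 1D-CNN table depend on an
  unspecified head and are treated as documentation, not targets.
* Early-stopping ties favor later epochs (see Training protocol); with a
  noisy monitor this returns the last plateau visit rather than the
  first.
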