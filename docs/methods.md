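# Methods

## Problem and approach

`ecgmae` implements self-supervised pretraining for 12-lead
electrocardiograms with a masked autoencoder (MAE), and the downstream
protocol that turns the pretrained encoder into a screening classifier
for left ventricular systolic dysfunction (LVSD, echocardiographic
ejection fraction below 40%).

A 10-second, 500 Hz record is a 12x5000 voltage matrix.  Treating it as
a one-channel image of shape 1x12x5000 and cutting patches of size
1x250 yields a 12x20 grid — 240 patches of half a second each, flattened
lead-major (patches 0..19 are lead I and so on; patch *i* of a lead
covers the half-open window `[250 i, 250 (i+1))`).  During pretraining a
masking plan hides a fraction *r* of the patches; only the visible
patches (plus a classification token) enter the ViT encoder, and a
lightweight decoder receives the full 240-token sequence — encoded
tokens at visible positions, a learned mask token elsewhere — and
regresses the 250 voltage values of every patch.  The loss is the mean
squared error over masked patches only.  Masking strategies:

* **random** — seeded uniform shuffle, `round(240 r)` patches hidden;
* **per-lead** — the same ratio applied independently within each lead
  (`round(20 r)` hidden per lead);
* **grid** — a regular keep-one-in-four stripe along time, defined for
  r = 0.75 only: visible iff the time index is congruent to a
  seed-chosen phase modulo 4.  The published work referenced figures we
  treat as underdetermined; this regular stripe is our documented
  interpretation of grid sampling, restricted to the one ratio at which
  it is exact.

Visible-count rounding is `round(N (1 - r))`; the studied ratios
(50/75/90%) all give integers (120/60/24 visible of 240).

## Model

The encoder is a standard pre-norm ViT: a linear projection of each
250-sample patch to the embedding width, a classification token, fixed
(untrained) 2-D sinusoidal positional embeddings over the (lead, time)
grid — half the channels encode the lead coordinate, half the time
coordinate — transformer blocks (multi-head self-attention plus a
4x MLP, GELU), and a final layer normalisation.  Size presets follow the
ViT family: Tiny (192, 4 blocks, 3 heads) for desk-scale work,
Base (768, 12, 12), Large (1024, 24, 16), Huge (1280, 32, 16).  The
closed-form parameter count of the Base encoder here is 85.2 M; the
commonly quoted "about 86 M" for ViT-Base additionally counts an image
model's learned positional table and 1000-way classification head,
which this ECG encoder does not carry.

The decoder mirrors the original MAE design: linear projection of the
encoder tokens to the decoder width, mask-token insertion, its own fixed
sinusoidal positional code, transformer blocks and a linear head back to
250 output channels.  The default decoder is 512-wide and 8 blocks deep;
a light preset (64-wide, shallower) is used throughout the desk-scale
experiments, where reconstruction pressure, not decoder capacity, is the
point.  The classification token passes through the decoder and is
dropped from the output.

Two contracts are load-bearing and tested explicitly: the encoder
output is a pure function of the visible patches, their grid positions
and the parameters (changing masked-patch contents cannot change it),
and the loss is invariant to predictions at visible positions.

All tensors are float32; the network, backpropagation, AdamW, and
gradient clipping are implemented directly on NumPy (BLAS matrix
products, numba-fused softmax/layer-norm/GELU kernels) and are verified
against central finite differences in float64.  Initialisation is
truncated-normal (resampled into two standard deviations, std 0.02) for
weights and tokens, zeros for biases; everything is seeded and
single-device deterministic.

## Training protocols

**Pretraining** draws a fresh random mask per record per epoch from a
seeded stream, takes AdamW steps (betas 0.9/0.95, weight decay 0.05) on
the masked-patch MSE, clips gradients at global norm 1.0, and follows a
linear-warmup-plus-cosine schedule with base rate 1.5e-4 scaled by
batch/256.  The published run trained Base/Large/Huge for 1600 epochs at
batch 1536/1280/768 with a 40-epoch warmup; those remain the config
defaults.  Desk-scale experiments here use the Tiny encoder, 30 epochs,
batch 32, base rate 8e-3 (effective 1e-3) and a 3-epoch warmup — sized
so a full pretrain-plus-fine-tune comparison completes on one CPU core.

**Fine-tuning** attaches a head to the encoder — mean over patch tokens
after the final layer norm (classification-token pooling available as a
flag), then `Linear(d, 128) -> GELU -> Linear(128, k) -> sigmoid` — and
minimises binary cross-entropy with Adam.  The hidden width 128 mirrors
the feature width of the reference CNN baseline; the monitored quantity
is the validation loss, since best-epoch weight saving implies held-out
monitoring.  The plateau rule: a strict improvement of the monitored
loss resets the non-improvement counter (ties count as
non-improvements); every 3 consecutive non-improving epochs halve the
learning rate; 10 consecutive non-improving epochs stop training; the
weights of the best epoch are restored.  Halving at every multiple of 3
within one plateau is our reading of the stated rule; halve-once-per-
plateau is the alternative, and the schedule function is pure and
swappable.  The search grid (batch in {32, 64, 128, 256}, initial rate in
{1e-3..1e-6}) is implemented with best-cell selection by lowest
validation loss at the best epoch; desk-scale runs use the single cell
batch 32, rate 1e-3.

## Cohort construction

Echo exams are paired one-to-one with ECGs of the same patient: echoes
processed in chronological order, each taking the unconsumed ECG with
the smallest `|days between|` within 28 days, ties broken toward the
earlier ECG.  (The consumption order and tie-break are our documented
determinism choices; the source protocol states only nearest-within-28-
days one-to-one pairing.)  Pairs missing the ejection fraction are
dropped; EF < 40% labels LVSD = 1.  Splits are assigned per *patient*
(shuffled by a seeded generator, cut at cumulative ratios 0.7/0.15/0.15)
so no patient contributes to two splits.

Normalization is a per-lead z-score; a lead whose standard deviation
falls below `max(1e-8 * max|x|, 1e-8)` is returned as zeros.  No
filtering, baseline-wander removal or augmentation is applied anywhere.
Per-lead (rather than whole-record) scaling is a documented choice; the
source states only that normalized ECGs were input.

## Synthetic cohorts

The generator exists so every downstream stage is testable without
hospital data.  Each patient owns a Gaussian-bump beat (P, Q, R, S, T
bumps with per-patient amplitude jitter), a 12-entry projection vector
mimicking limb/precordial polarities, a heart rate drawn around
68 +/- 8 bpm, and an echo exam dated within 28 days of 1–3 ECGs
(probabilities 0.75/0.20/0.05).  Records are beats with jittered RR
intervals, projected to 12 leads, plus 0.3 Hz sinusoidal baseline wander
(0.1 mV) and white noise (0.05 mV), trimmed to exactly 5000 samples.

Ejection fractions for non-LVSD patients are drawn from a normal with
mean 61.6 and SD 14.2 — the registry-scale moments — truncated to
[40, 95); LVSD patients (prevalence 0.083 by default) draw uniformly
from 15–39.5.  The LVSD morphology shift scales with `effect_size` e:
R amplitude times `1 - 0.4 e (1 - EF/60)`, QRS widths times
`1 + 0.5 e`, heart rate plus `10 e` bpm.  At e = 0 the two groups are
statistically identical (the null used by the integrity tests); e = 1 is
the default study condition.  This parameterisation is invented and
version-pinned so the learnability experiments are stable.

What the generator does *not* emulate: real conduction physiology,
vectorcardiographic consistency between leads, arrhythmias, electrode
artefacts, or inter-device differences.  Passing tests therefore show
that the pipeline can extract a morphology signal of this kind — not
that any clinical performance level would be reached on hospital data.

## Desk-scale experiment sizes

The headline mechanism — pretraining helps when labels are scarce — is
exercised at a deliberately small scale chosen as a compromise between
statistical resolution and a single-core run: a 400-patient cohort
(about 500 records), Tiny encoder with the light decoder, 30 pretraining
epochs, fine-tuning on 100 labeled records with validation-loss early
stopping (at most 15 epochs), and a pretrained fine-tune compared with
random-initialisation controls over 3 fine-tuning seeds.  At this scale
pretraining runs for roughly five hundred optimizer steps — orders of
magnitude fewer than a converged masked-autoencoder schedule — so the
reconstruction error stays near the z-scored noise floor and the
transfer benefit, not the absolute classification ceiling, is the
quantity the experiment resolves.  The DeLong null calibration uses
1000 replicates at n = 500; AUROC oracle equivalence uses exact
brute-force concordance counting at n <= 200.

## Numerical conventions and degenerate cases

* AUROC is the midrank Mann–Whitney estimator; ties count one half.
  The naive O(n+ n-) pair count is kept as a test oracle, and the fast
  midrank DeLong components double as the variance machinery.
* Perfect separation gives zero DeLong variance: the confidence interval
  degenerates to the point estimate and is flagged rather than widened.
  Identical paired scores give z = 0, p = 1.  Intervals are clipped to
  [0, 1] (a logit transform is deliberately not applied; flag-switchable).
* Multi-label macro-AUC skips classes lacking both label values in the
  evaluation set and reports the skips; repeated runs print as
  `mean (SD-last-two-decimals)`, e.g. `0.960 (02)`.
* Masked-loss with an empty masked set, single-class AUROC, grid masking
  away from r = 0.75, and non-500 Hz records without resampling opt-in
  are all errors, not silent fallbacks.
* WFDB support covers the format-16 header/signal pairs used by public
  ECG archives; channel order is remapped to the canonical lead order by
  name.

## Known limitations

* The transformer runs on CPU; Large/Huge presets are constructable and
  countable but not practically trainable here.
* The grid-masking stripe and the plateau-halving cadence are stated
  interpretations where the source is ambiguous; both are isolated
  behind small, documented functions.
* The synthetic LVSD signal is a single morphology axis; multi-label
  statement tasks on the PTB-XL-layout path use fabricated statement
  codes on synthetic signals and exercise plumbing, not clinical
  difficulty.
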