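# Methods

## Overview

`emoconn` implements an EEG emotion-recognition pipeline in four stages:

1. **Preprocessing** — 4–45 Hz zero-phase band-pass (4th-order
   Butterworth, forward–backward), removal of the first 3 s pre-stimulus
   baseline, and sliding-window segmentation (3-s windows, 0.5-s step by
   default). On the 63-s/128-Hz trial geometry this yields 115 windows
   of 384 samples per trial. Affect ratings on the 1–9 scale are
   binarized at the midpoint: ratings > 5 are the high class.
2. **Connectivity features** — per window, an N×N matrix from one of
   four pairwise measures (below), with rows/columns arranged under an
   explicit electrode order.
3. **Electrode ordering** — a greedy nearest-neighbour scalp-distance
   chain ("dist" mode; the published 32-electrode chain ships as a
   canonical constant), or one-dimensional scaling on a connectivity
   matrix ("global"/"local" modes).
4. **Classification** — a residual CNN over the connectivity matrix (or
   a Welch log-PSD matrix), optionally trained adversarially against a
   domain discriminator through a gradient-reversal layer (GRL).

## Connectivity measures

For channels i, j with window samples s_i^t (t = 1..T):

* **PCC**: (1/T) Σ_t (s_i^t−μ_i)(s_j^t−μ_j) / (σ_i σ_j), with μ and σ
  the per-channel mean and (1/T-normalized) standard deviation, so the
  diagonal is exactly 1. Range [−1, 1].
* **PLV**: |(1/T) Σ_t exp(i(φ_i^t − φ_j^t))| with instantaneous phases
  φ from the analytic (Hilbert) signal of the band-passed window. The
  analytic signal is computed on the full window without padding; edge
  effects are accepted rather than hidden because windows are short.
  Range [0, 1].
* **TE** (directed): plug-in transfer entropy. Channels are discretized
  into `n_bins` (default 8) equal-frequency symbols built on ranks —
  hence invariant under strictly monotone transforms. Joint counts of
  (s_i^t, s_j^t, s_j^{t+1}) give
  TE(i→j) = Σ p(a,b,c) log2 [ p(c|a,b) / p(c|b) ], the time-average of
  the observed log-ratios. First-order embedding only; diagonal 0.
  Plug-in estimates are biased upward at small T (a warning fires when
  n_bins³ > T); tests compare against the enumerated limit of a
  deterministic copy process (exactly 1 bit).
* **WCC**: wavelet coherence from a complex Morlet CWT (centre
  frequency ≈ 0.955 in normalized units, the ω₀ = 6 convention), 24
  log-spaced scales covering 4–45 Hz. Cross- and auto-spectra are
  smoothed by a Gaussian in time (σ = 0.6·scale samples) and a 3-point
  boxcar across scales; coherence |S_xy|²/(S_xx S_yy) is averaged over
  all scales and times into one scalar per pair. With this light
  smoothing the independent-noise baseline is visibly above zero (a
  known small-sample property of smoothed coherence), so tests assert
  relative contrasts, not absolute levels.

## Electrode ordering

*dist mode.* Starting at the left frontal pole (Fp1), repeatedly append
the nearest unvisited electrode (Euclidean distance in the bundled 2-D
projected layout; ties break by ascending label). No standard
coordinate table reproduces the published DEAP-32 chain exactly, so that
chain ships as the canonical constant used for DEAP-layout data, and the
greedy algorithm is exercised on constructed geometries.

*global / local modes (UDS).* Disparities δ = 2(1−c) (global; an
optional flag switches to the conventional √(2(1−c))) or δ = c²
(local) are fit by minimizing the normalized stress
Σ_{i<j}(|l_i−l_j|−δ_ij)² / Σ_{i<j}δ_ij² over scalar coordinates
l₁..l_N. The landscape is multimodal; minimization is multi-start
L-BFGS-B with an analytic (sub)gradient, default 20 seeded restarts,
keeping the best. Only the rank order of the embedding is kept, and it
is canonicalized against reflection (first index smaller than last).
Directed (TE) inputs are symmetrized as (M+Mᵀ)/2 with a warning.

## Classifier

Input is one N×N matrix (single channel). Stem convolution (32 filters
full-scale), then r residual blocks y = F(x)+x with
F = BN(conv(ReLU(BN(conv(x))))), stride 1, same padding; a 1×1
projection (conv+BN) is used on the shortcut exactly when the channel
count grows (full-scale widths 32/64/128) — the stated architecture
grows channels at stride 1, which the identity shortcut cannot match.
No activation follows the addition, so a zero-weight block is exactly
the identity. The flattened features feed two dense layers (1024/512
full-scale, sigmoid activation, dropout 0.2 after each — ReLU available
behind a flag) and a softmax head. Ties in the arg-max resolve to the
lower class index.

The network, its gradients and the Adam optimizer are implemented
directly on numpy (channels-last layout; convolution as k² shifted BLAS
products). Gradient correctness is verified against finite differences
in the test suite.

**Domain adaptation.** A discriminator head (dense 256 → ReLU → dense 2
softmax at full scale) receives the flattened features through a GRL:
identity forward, gradient × −λ backward. One fused Adam step per batch
minimizes L = L_y − L_d: the source rows of the concatenated batch
contribute the label cross-entropy L_y, all rows contribute the domain
cross-entropy L_d, and the GRL makes the feature extractor ascend L_d
while the discriminator descends it. λ defaults to 1.0; the standard
warm-up schedule λ(p) = 2/(1+e^{−10p}) − 1 over training progress p is
available (`grl_schedule="dann"`). Training-loop losses use mean
reduction so learning rates are batch-size independent; the standalone
loss functions default to the sum form.

Two options matter at small sample counts. ``disc_dropout`` applies
heavy dropout (0.8 in the scaled protocol) to the discriminator input:
with a few hundred windows in an 8192-dimensional feature space a free
discriminator simply memorizes which windows are source and which are
target, its loss collapses to zero, and the reversed gradient stops
carrying distribution-level information; input dropout forces it to
generalize, keeping the adversarial signal meaningful.
``target_batch_size`` lets every step show the discriminator the whole
unlabelled target set rather than a mini-batch slice, which stabilizes
the alignment statistics when the target fold is small.  A
``avg_tail`` option averages the parameters of the last epochs
(Polyak-style) before prediction to damp final-step jitter.

Adaptation is **transductive**: the unlabelled inputs of the evaluation
fold are the target domain during training. Their labels are never
read — the fit API has no parameter that could carry them — and a
leakage audit checks that no (subject, trial, window-start) identity
appears on both sides of any fold.

## Cross-validation and metrics

*Subject-dependent*: within each subject, trials are shuffled (seeded)
into 10 folds (≈10% of trials each); windows follow their trial.
*LOSO*: one fold per subject. Metrics are confusion-count specificity
TN/(TN+FP), sensitivity TP/(TP+FN) and accuracy, with class 1 (high
affect) as positive. Each fold re-initializes the model from the seed;
there are no warm starts.

Full-scale optimization settings follow the published protocol: Adam,
learning rate 0.001 / batch 40 / 200 epochs (subject-dependent) and
0.005 / batch 128 / 150 epochs (LOSO), with 0.0001 retained as the
documented fallback initial rate.

## Synthetic data generator

Each trial is band-limited noise (4–45 Hz) per channel plus, on a
designated coupled channel subset, a shared band-limited source mixed
with weight κ: κ₁ = 0.7 for high-affect trials, κ₀ = 0.3 otherwise
(gap 0.4). The source occupies the same 4–45 Hz band as the noise by
default, so the class is carried almost entirely by *coupling* rather
than by any spectral signature a per-channel power feature could read.
The first 3 s stay uncoupled (baseline). Half of the coupled channels
receive the source delayed by 2 samples so transfer entropy has a
testable direction. Ratings are drawn uniform (6, 9] for class 1 and
[1, 5] for class 0, so midpoint binarization recovers the class
exactly.

Per-subject domain shift, drawn once per subject: amplitude gain
(0.6–1.6), idiosyncratic-noise multiplier (0.7–1.4), spectral tilt
(amplitude × (f/10 Hz)^(tilt/2), tilt ∈ ±1.5), a **coupling-level
offset** δ ∈ ±0.2 added to both class κ levels (so one subject's
classes sit at (0.1, 0.5) and another's at (0.5, 0.9) while the
within-subject contrast stays 0.4), and optionally a
background-synchrony level (off by default). After mixing, every
channel is normalized to equal variance: the class signal lives in
cross-channel coupling, not in single-channel power.

The coupling-level offset is the shift axis that makes the
domain-adaptation comparison meaningful, and the reasoning is worth
recording. Gain and tilt barely touch instantaneous phase, so
phase-locking features are nearly invariant to them; a global synchrony
offset is a relative pattern the convolutional classifier absorbs; and
a strong SNR shift partially *destroys* class information in the
affected subject — no feature alignment can restore information that
is gone, so adversarial adaptation helps only erratically against it.
A coupling-level offset, by contrast, translates the informative
feature (coupled-block synchrony) per subject while preserving the
class contrast: a classifier trained on other subjects mis-places its
decision threshold, and aligning feature distributions to the
unlabelled target recovers exactly that loss. It also has a natural
reading: individuals differ in overall functional-connectivity
strength.

What the generator does *not* emulate: volume conduction, 1/f spectra
fit to real EEG, artifacts, or non-stationarity beyond the baseline
switch. Passing tests therefore demonstrate correct mechanics and the
qualitative benefit of connectivity features and domain adaptation
under controlled shift — not performance on real EEG.

## Scaled study protocol

Desk-scale runs (tests, `scripts/acceptance.py`) use 4 subjects × 8
trials of 63-s recordings; 3-s windows on a 3-s step, with training
restricted to every second window (10 per trial) while evaluation uses
every window of the held-out trials or subject; a one-block model
(r=1, 3×3 kernels, 8 stem filters, dense 64/32, discriminator hidden
64, DANN λ warm-up); Adam 1e-3; batch 64, 12 epochs for LOSO runs and
batch 40, 30 epochs for subject-dependent runs. Subject-dependent folds hold out
2 of 8 trials (4 folds). These sizes are the package's study design for
CPU-scale experiments; the full-scale defaults above remain available
through configuration.

A note on the variant comparison at this scale: across synthetic
cohorts the mean leave-one-subject-out accuracies order as
PSD < connectivity < connectivity + adaptation with per-cohort
adaptation margins typically between +0.5 and +9 accuracy points under
the coupling-offset shift. On individual cohorts the ordering can
still flip by one or two windows — when the non-adaptive model is
already at ceiling the adversarial branch can only tie, and on cohorts
where subject offsets make neighbouring classes overlap exactly, the
baselines themselves become unstable — so the ordering is asserted
over a majority of cohorts, not each one.

## Numerical notes and limitations

* Windowing arithmetic is sample-exact; window/step lengths must be
  whole samples at the recording rate.
* PCC/PLV matrices are clipped to their theoretical ranges to absorb
  float round-off; TE is clipped at 0.
* The stress objective is non-smooth at coincident coordinates;
  L-BFGS-B handles the subgradient in practice, and multi-start
  restarts make order recovery robust on exactly-embeddable instances.
* Equal-frequency TE binning resolves rank ties by (stable) sample
  order; continuous signals are unaffected.
* The parameter count of the full-scale architecture is dominated by
  the flatten → dense-1024 stage (tens of millions of weights); the
  scaled profile avoids it with narrow dense layers.
* Training histories log (epoch, L_y, L_d, L, acc) and satisfy
  L = L_y − L_d identically; with adaptation disabled L_d ≡ 0.
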