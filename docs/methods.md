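# Methods

This note documents the models, numerical choices and known limitations of
`icgn-bci`. It is the package's own account of what it computes; every
empirical number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## Recurrent cells

Two cells are implemented from scratch in double precision.

**LSTM.** The standard gated cell: input, forget and output gates are
sigmoids of `W_x x_t + W_h h_{t-1} + b`, the candidate is a tanh of the same
form, and the memory state updates additively,
`C_t = F_t ⊙ C_{t-1} + I_t ⊙ G_t`, with `H_t = O_t ⊙ tanh(C_t)`.

**Integrated contextual gate (ICGN).** Every gate and the candidate receive
the previous *cell* state through an additional `H×H` context matrix, and
the memory update replaces the additive carry with a sum-of-gates scaling of
the candidate:

    C_t = (F_t + I_t + O_t) ⊙ G_t,      H_t = O_t ⊙ tanh(C_t)

There is deliberately **no** direct `C_{t-1}` term in the update; the
previous cell state influences the future only through the gate and
candidate pre-activations. Two properties follow immediately and are
enforced by property tests:

* `|C_t| < 3` elementwise (three gates each `< 1`, candidate `|G| < 1`) and
  `|H_t| < tanh(3) ≈ 0.995`. The bound is strict in exact arithmetic; in
  float64 `tanh` saturates to exactly `±1.0` for `|z| ≳ 19`, so the
  randomized strict test bounds its draws below saturation and a separate
  stress test asserts the closed-interval bound under deliberate saturation.
* with zeroed context matrices the ICGN gates coincide with the LSTM gates
  on identical inputs (the state trajectories still differ through the
  update rule).

**Parameterisation choices.** The source formulation writes the candidate
with the forget gate's weight symbols and reuses the forget-gate context
matrix inside the output gate. Both readings are supported: by default the
candidate has its own parameters (`wxc, whc, wcc, bc`) and the output gate
its own context matrix (`wco`) — the expressive, standard choice — while
`share_candidate_with_forget` and `share_output_context_with_forget` alias
the arrays to reproduce the literal equations (aliased arrays are the same
ndarray, and their gradients accumulate jointly, which the finite-difference
check verifies). The candidate's cell-context term can likewise be dropped
(`candidate_uses_cell_context=False`) to match the reading in which the
internal state depends only on the input and previous hidden state. Context
matrices are full `H×H` (matrix-product convention) with a diagonal
initialisation option in the spirit of classic peephole cells.

**Gradients.** Backpropagation through time is hand-derived for both cells,
including the alias-folding cases. The check metric is the norm-based
per-array relative error `‖g − g_fd‖ / max(‖g‖, ‖g_fd‖)` against central
finite differences (ε = 1e−6); elementwise ratios were not used because they
are ill-conditioned wherever a gradient entry is near zero. Measured errors
are ~1e−8 for `T ≤ 8`, `H ≤ 4` (threshold 1e−5).

## Classifier and training

All three classifiers (LSTM, ICGN, bidirectional LSTM) share one head for
comparability: recurrent layer (final hidden state; concatenated
forward/backward states for the bidirectional model) → inverted dropout →
dense ReLU → dense softmax (sigmoid optional). Defaults follow the
best-performing region of the hyperparameter discussion: 64 recurrent units,
dropout 0.2, dense 64, learning rate 0.001, batch 32, categorical
cross-entropy, 100 epochs, Adam (plain SGD available). Training is seeded
end-to-end — initialisation, shuffling and dropout masks derive from one
generator — so histories are exactly reproducible.

Because the labeling is per time point while recurrent cells consume
sequences, each labeled sample becomes a causal window of `W = 20`
consecutive time points (~2 s at 10.1725 Hz) ending at that sample. Windows
never cross a segment boundary; positions before the segment start replicate
its first sample. This keeps the per-condition sample counts identical to
the per-time-point counting below.

## Preprocessing

**Beer-Lambert conversion.** `[ΔHbO, ΔHbR]ᵀ = E⁻¹ [ΔA(λ₁), ΔA(λ₂)]ᵀ/(l·d)`
per time point and channel, with `E` the 2×2 extinction matrix, `l = 3 cm`
source-detector separation and differential path-length factor `d = 6.0`
(conventional adult value; configurable). Extinction defaults are tabulated
literature values for 760/850 nm in µM⁻¹cm⁻¹; all tests use synthetic
tables so no result depends on that choice. A condition number above 1e6
triggers a warning. The exact algebraic inverse is provided so the simulator
can emit raw-style absorbance.

**Band-pass filter.** 4th-order Butterworth, 0.01–0.2 Hz, applied
forward-backward (zero phase; order/type configurable). The 0.01 Hz edge
implies an impulse response of hundreds of seconds, so reflective padding is
extended to `3/low` seconds; frequency-response checks are made in steady
state, trimming a 30 s settle interval from each edge of a 360 s record.
Measured: 0.37% RMS at 1 Hz (stop band), 100.0% at 0.05 Hz (pass band),
peak lag ≤ 1 sample in band.

**Segmentation and counting.** The block paradigm is 30 s baseline, ten
trials of 10 s activity + 20 s rest, 30 s baseline (360 s). Per-condition
sample counts are fixed as `floor(total condition duration × fs)` and then
apportioned over that condition's segments by largest remainder; samples are
consumed from the series in temporal order (0-based, half-open segments).
This is the one simple rule consistent with the printed per-condition counts
at 10.1725 Hz — 610 baseline, 1017 activity, 2034 rest, 3661 total — even
though `floor(360 × 10.1725) = 3662`; the last acquired sample is simply
never labeled. Baseline is excluded from classification; within-trial rest
is the first class, activity the second.

**Splitting.** Classes are first equalised by randomly subsampling the
majority class per trial ("an equal number of samples per class"), then each
class is split 80/10/10 with largest-remainder quotas *per trial segment*,
so every partition draws from every trial, partitions are disjoint and
exhaustive over the balanced subset, and per-partition class counts agree to
within one sample. Covering *all* samples while balancing every partition is
arithmetically impossible at the paradigm's 1:2 class ratio, which is why
balancing-by-subsampling was chosen.

## Synthetic data

The simulator emulates a block-design motor-task recording: each task
condition's boxcar is convolved with a canonical double-gamma HRF (peak
6 s, undershoot 16 s, dispersions 1 s, undershoot ratio 1/6; each gamma
lobe parameterised so its mode sits at the configured delay; kernel
truncated at 32 s and scaled so a sustained block reaches the configured
amplitude, default 1 µM — a typical task-evoked ΔHbO excursion). The
response is projected onto 8 of 20 channels with weights tapering 1.0→0.5;
ΔHbR is −⅓·ΔHbO plus noise. Additive noise comprises white noise (SD 0.1 µM
= 10% of the response amplitude, the "high-SNR" condition), sinusoidal
physiology (Mayer ~0.1 Hz, respiration ~0.3 Hz, cardiac ~1.0 Hz, amplitude
0.1 µM each, random phase per channel) and a small linear drift
(~0.001 µM/s). Cohorts derive per-subject seeds from a master seed and apply
log-normal (σ = 0.2) jitter to amplitude and noise SD.

What the simulator does **not** model: motion-artifact spikes, photon
transport, superficial/systemic components shared across channels, or
habituation across trials. Passing tests therefore demonstrate that the
pipeline recovers a known hemodynamic pattern under realistic stationary
noise — not performance on real recordings.

**A note on sample-wise splits.** After band-pass filtering, the signal and
noise are smooth on the ~5 s scale, and a random per-time-point split places
nearly identical neighbouring windows in train and test. With the
hemodynamic amplitude set to zero, a linear classifier still scores ~69%
under the sample-wise split purely by memorising noise trajectories — a
temporal-leakage artifact well known for this evaluation style. Held-out
*trials* score at chance, which is how the "no signal ⇒ chance" property is
tested. The chance-level control used in acceptance is cleaner still:
shuffling the labels breaks the alignment entirely and validation accuracy
stays at 50 ± 10% (measured ~48–53%).

## Statistics

Accuracy/confusion, pooled-variance two-sample t (Welch optional), classical
one-way ANOVA, and Tukey HSD with the Tukey-Kramer standard error and
p-values from scipy's studentized-range distribution. Sum-of-squares terms
are computed directly and cross-checked in tests against
`scipy.stats.f_oneway`, `ttest_ind` and statsmodels' `pairwise_tukeyhsd`.
For two groups, `F = t²` to 1e−8 relative. Statistics are kept at full
precision internally and rounded only for display.

The bundled 20-subject benchmark table reproduces the published cohort
statistics exactly: F(2, 57) = 28.73, p = 2.35e−9; Tukey mean differences
−3.953 (BiLSTM→LSTM), 2.437 (BiLSTM→ICGN), 6.39 (LSTM→ICGN); LSTM
84.89 ± 3.91%, ICGN SD 1.60%, BiLSTM SD 1.96%. The table's printed ICGN and
BiLSTM averages (91.23, 88.82) differ by ~0.05 from the exact means of its
own per-subject values (91.28, 88.84); the package always reports exact
recomputation.

## Problem sizes used in checks

The acceptance script classifies a 5-subject high-SNR cohort (full 360 s
paradigm, 20 channels, 16 recurrent units, 100 epochs) plus a shuffled-label
control subject (40 epochs); the test suite runs a 3-subject version. Both
sizes give a wide margin on the ≥ 85% recovery threshold (measured 100%
mean test accuracy). Gradient checks use `T ≤ 8`, `H ≤ 4`; the state bound
is sampled over 1000 randomized steps.

## Known limitations

* The update `C_t = (F+I+O) ⊙ G_t` bounds the memory state but also means
  information persists only through the gate pre-activations, not through an
  additive carry; very long dependencies decay accordingly. This is the
  method's defining design choice, implemented literally.
* One-way ANOVA treats subjects as independent between algorithm groups; a
  repeated-measures design would be more appropriate for per-subject paired
  accuracies but is out of scope.
* The SNIRF reader/writer covers a minimal subset (one data block,
  per-channel measurement lists) sufficient for round-tripping the
  package's own series, not the full standard.
* Bidirectional wrapping is provided for the LSTM only; a bidirectional
  contextual-gate variant is left to future work.
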