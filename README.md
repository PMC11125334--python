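# icgn-bci

Classification of functional near-infrared spectroscopy (fNIRS)
brain-computer-interface signals with an **integrated contextual gate
network (ICGN)** — a recurrent cell in which all three gates and the
candidate receive the previous cell state, and the memory update is the
candidate scaled by the *sum* of the gate activations:

    I_t = σ(W_xi x_t + W_hi h_{t-1} + W_ci c_{t-1} + b_i)
    F_t = σ(W_xf x_t + W_hf h_{t-1} + W_cf c_{t-1} + b_f)
    O_t = σ(W_xo x_t + W_ho h_{t-1} + W_co c_{t-1} + b_o)
    G_t = tanh(W_xc x_t + W_hc h_{t-1} + W_cc c_{t-1} + b_c)
    C_t = (F_t + I_t + O_t) ⊙ G_t          (no direct C_{t-1} carry)
    H_t = O_t ⊙ tanh(C_t)

A direct consequence is the bound `|C_t| < 3`, `|H_t| < tanh(3)` for any
weights and inputs. The package implements this cell and a standard LSTM
from scratch (NumPy, with hand-derived backpropagation through time verified
against finite differences), the full fNIRS classification pipeline around
them, and the cohort-level statistical comparison:

* **preprocessing** — modified Beer-Lambert conversion of two-wavelength
  absorbance to ΔHbO/ΔHbR, zero-phase 0.01–0.2 Hz Butterworth band-pass,
  block-paradigm segmentation/labeling (30 s rest, 10 × [10 s activity +
  20 s rest], 30 s rest at 10.1725 Hz → 610/1017/2034 samples), balanced
  80/10/10 splits;
* **network** — LSTM / ICGN / Bi-LSTM classifiers (recurrent layer →
  dropout → dense ReLU → softmax), seeded Adam training, hyperparameter
  sweeps;
* **synthetic** — block-design simulator (double-gamma HRF, physiological
  noise, per-subject variability) with exact ground-truth labels;
* **stats** — accuracy/confusion, pooled t-test, one-way ANOVA, Tukey HSD;
* **cli** — `icgn-bci simulate | preprocess | train | run | stats | sweep |
  verify-reference-stats`.

Intended users: BCI/neuroimaging researchers who want a transparent,
dependency-light reference implementation of contextual-gate recurrent
classification that is fully testable without access to any recordings.

## Worked example

Simulate a small high-SNR cohort, train the contextual-gate classifier and
an LSTM baseline on every subject, and compare them:

```python
from icgn_bci import network, pipeline

ncfg = network.NetworkConfig(cell_kind="icgn", recurrent_units=16, dense_units=32)
tcfg = network.TrainingConfig(epochs=100, seed=0)
results = pipeline.run_cohort(3, ["icgn", "lstm"], net_config=ncfg,
                              train_config=tcfg, master_seed=42)
print(results.round(2))
```

```
       icgn   lstm
sub1  100.0  100.0
sub2  100.0  100.0
sub3  100.0  100.0
```

Each row is one simulated subject; each value is held-out test accuracy (%)
on the balanced 10% test partition (204 windows). At this signal-to-noise
ratio (hemodynamic amplitude 10× the white-noise SD) both cells solve the
task; the simulator's noise amplitude can be raised to make the comparison
harder.

The statistics module reproduces the published 20-subject benchmark
comparison from the bundled accuracy table:

```bash
icgn-bci verify-reference-stats
```

prints the recomputed column summaries (LSTM 84.89 ± 3.91%, ICGN
91.28 ± 1.60%, Bi-LSTM 88.84 ± 1.96%), the one-way ANOVA
`F(2,57) = 28.732, p = 2.346e-09`, and the Tukey HSD pairs
(LSTM→ICGN 6.39, BiLSTM→ICGN 2.437, BiLSTM→LSTM −3.953, all rejected at
α = 0.05).

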