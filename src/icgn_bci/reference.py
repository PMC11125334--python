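"""Published benchmark reference values for the two-class hand-gripping task.

The bundled CSV holds the subject-wise test accuracies reported for the
LSTM, ICGN and Bi-LSTM classifiers on a 20-subject hand-gripping fNIRS
benchmark.  Recomputing the cohort statistics (column means/SDs, one-way
ANOVA F, Tukey HSD mean differences) from this table reproduces the
published summary statistics and serves as a deterministic regression check
on the statistics module.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Summary statistics as printed alongside the benchmark table (accuracy in %).
PUBLISHED_SUMMARY = {
    "anova_f": 28.731,
    "anova_p": 2.346e-9,
    "tukey_meandiff": {
        ("BiLSTM", "LSTM"): -3.953,
        ("BiLSTM", "ICGN"): 2.437,
        ("LSTM", "ICGN"): 6.39,
    },
    "tukey_p_adj": {
        ("BiLSTM", "LSTM"): 0.0001,
        ("BiLSTM", "ICGN"): 0.0159,
    },
    "column_mean": {"LSTM": 84.89, "ICGN": 91.23, "BiLSTM": 88.82},
    "column_sd": {"LSTM": 3.91, "ICGN": 1.60, "BiLSTM": 1.96},
}

ALGORITHMS = ("LSTM", "ICGN", "BiLSTM")


def load_two_class_accuracies() -> pd.DataFrame:
    """Subject-wise accuracy table (rows: subjects 1-20; columns: LSTM, ICGN, BiLSTM)."""
    with resources.files("icgn_bci.data").joinpath("two_class_subject_accuracies.csv").open() as fh:
        return pd.read_csv(fh, index_col="subject")
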