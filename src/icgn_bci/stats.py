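"""Evaluation statistics: confusion/accuracy, pooled t-test, one-way ANOVA and
Tukey HSD post hoc comparisons.

The ANOVA uses the classical fixed-effects decomposition
``F = MS_between / MS_within`` with ``df = (k-1, N-k)``; Tukey HSD adjusts the
pairwise comparisons through the studentized range distribution with the
Tukey-Kramer standard error for unequal group sizes.  Sum-of-squares terms
are computed directly here; only the reference distributions (t, F,
studentized range) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "ConfusionMatrix",
    "AnovaResult",
    "TukeyResult",
    "confusion_and_accuracy",
    "two_sample_ttest",
    "one_way_anova",
    "tukey_hsd",
    "summarize_cohort",
]


@dataclass
class ConfusionMatrix:
    """k x k counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / self.total


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: np.ndarray
    ms_within: float


@dataclass
class TukeyResult:
    """Pairwise comparisons: mean difference is group2 - group1; reject at p_adj < alpha."""

    table: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    alpha: float


def confusion_and_accuracy(
    true_labels: np.ndarray, predicted_labels: np.ndarray, k: int
) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix and overall accuracy (%) for integer labels in [0, k)."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label arrays must be 1-D and of equal length")
    if t.size == 0:
        raise ValueError("empty label arrays")
    if t.min() < 0 or t.max() >= k or p.min() < 0 or p.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (t, p), 1)
    cm = ConfusionMatrix(counts)
    return cm, cm.accuracy_percent


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, two_tailed: bool = True, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t-test; pooled-variance (Student) by default, Welch optional."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least two values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    if se == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("degenerate: zero variance in both samples with unequal means")
    t = diff / se
    p = 2.0 * spstats.t.sf(abs(t), df) if two_tailed else spstats.t.sf(t, df)
    return float(t), float(min(p, 1.0))


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least two values")
    return gs


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across independent groups."""
    gs = _check_groups(groups)
    k = len(gs)
    N = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    means = np.array([g.mean() for g in gs])
    ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in gs))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    dfb, dfw = k - 1, N - k
    msw = ssw / dfw
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else np.inf
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        f = (ssb / dfb) / msw
        p = float(spstats.f.sf(f, dfb, dfw))
    return AnovaResult(
        f_statistic=float(f),
        p_value=p,
        df_between=dfb,
        df_within=dfw,
        group_means=means,
        ms_within=msw,
    )


def tukey_hsd(
    groups: list[np.ndarray], names: list[str] | None = None, alpha: float = 0.05
) -> TukeyResult:
    """Tukey HSD post hoc comparisons after a one-way ANOVA.

    For each pair the studentized-range statistic is
    ``q = |m2 - m1| / sqrt(MS_within/2 * (1/n1 + 1/n2))`` and the adjusted
    p-value is the survival function of the studentized range with
    ``(k, N-k)`` parameters.
    """
    gs = _check_groups(groups)
    k = len(gs)
    if names is None:
        names = [f"group{i + 1}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names must match the number of groups")
    anova = one_way_anova(gs)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = gs[j].mean() - gs[i].mean()
            se = np.sqrt(anova.ms_within / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            if se == 0:
                p_adj = 1.0 if d == 0 else 0.0
            else:
                q = abs(d) / se
                p_adj = float(spstats.studentized_range.sf(q, k, anova.df_within))
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "meandiff": d,
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                    "reject": p_adj < alpha,
                }
            )
    return TukeyResult(table=pd.DataFrame(rows), alpha=alpha)


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Per-algorithm mean and sample (n-1) standard deviation of subject accuracies.

    ``table``: rows = subjects, columns = algorithms, values = accuracy (%).
    """
    if len(table) < 2:
        raise ValueError("need at least two subjects")
    vals = table.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 100):
        raise ValueError("accuracies must lie in [0, 100]")
    return pd.DataFrame(
        {"mean": table.mean(axis=0), "sd": table.std(axis=0, ddof=1)}
    )
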