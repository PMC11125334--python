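"""fNIRS preprocessing: optical-density to hemoglobin conversion, filtering,
block-paradigm segmentation/labeling, and balanced train/val/test splitting.

The modified Beer-Lambert law (MBLL) relates the absorbance change at two
near-infrared wavelengths to concentration changes of oxygenated and
deoxygenated hemoglobin:

    [dHbO, dHbR]^T = E^-1 [dA(l1), dA(l2)]^T / (l * d)

with ``E`` the 2x2 extinction-coefficient matrix, ``l`` the source-detector
separation (cm) and ``d`` the differential path-length factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "AbsorbanceSeries",
    "ExtinctionTable",
    "HemoglobinSeries",
    "ParadigmSchedule",
    "Segment",
    "LabeledDataset",
    "mbll_convert",
    "inverse_mbll",
    "bandpass_filter",
    "build_paradigm",
    "segment_and_label",
    "split_dataset",
    "class_difference_ttest",
    "DEFAULT_FS",
]

DEFAULT_FS = 10.1725
BASELINE = "baseline"

# Tabulated molar extinction coefficients in uM^-1 cm^-1 for the usual
# continuous-wave wavelength pair.  Row order: wavelength; column order:
# (HbO, HbR).  Analyses that depend on absolute concentration scaling should
# substitute their instrument's table.
DEFAULT_EXTINCTION = {
    760.0: (1.4866e-3, 3.8437e-3),
    850.0: (2.5264e-3, 1.7986e-3),
}


@dataclass
class ExtinctionTable:
    """Extinction coefficients (uM^-1 cm^-1) of HbO and HbR at the two wavelengths."""

    eps_hbo_l1: float
    eps_hbr_l1: float
    eps_hbo_l2: float
    eps_hbr_l2: float

    @classmethod
    def default(cls, wavelengths: tuple[float, float] = (760.0, 850.0)) -> "ExtinctionTable":
        (o1, r1), (o2, r2) = (DEFAULT_EXTINCTION[w] for w in wavelengths)
        return cls(o1, r1, o2, r2)

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.eps_hbo_l1, self.eps_hbr_l1], [self.eps_hbo_l2, self.eps_hbr_l2]]
        )

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


@dataclass
class AbsorbanceSeries:
    """Two-wavelength absorbance (optical-density) changes, (T, C, 2)."""

    delta_od: np.ndarray
    fs: float = DEFAULT_FS
    wavelengths: tuple[float, float] = (760.0, 850.0)
    source_detector_distance_cm: float = 3.0
    dpf: float = 6.0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.delta_od = np.asarray(self.delta_od, dtype=float)
        if self.delta_od.ndim != 3 or self.delta_od.shape[2] != 2:
            raise ValueError("delta_od must have shape (T, C, 2)")
        if self.fs <= 0 or self.source_detector_distance_cm <= 0 or self.dpf <= 0:
            raise ValueError("fs, source-detector distance and dpf must be positive")
        if not np.all(np.isfinite(self.delta_od)):
            raise ValueError("delta_od contains non-finite values")
        if self.channel_names is None:
            self.channel_names = [f"CH{i + 1}" for i in range(self.delta_od.shape[1])]

    @property
    def n_channels(self) -> int:
        return self.delta_od.shape[1]


@dataclass
class HemoglobinSeries:
    """Per-channel concentration changes dHbO/dHbR in uM, each (T, C)."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float = DEFAULT_FS
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 2:
            raise ValueError("hbo and hbr must be (T, C) arrays of equal shape")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channel_names is None:
            self.channel_names = [f"CH{i + 1}" for i in range(self.hbo.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]


@dataclass
class Segment:
    condition: str
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")


@dataclass
class ParadigmSchedule:
    """Ordered block-design segments (condition, duration in seconds)."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def condition_durations(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for s in self.segments:
            out[s.condition] = out.get(s.condition, 0.0) + s.duration
        return out

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.segments:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen


@dataclass
class LabeledDataset:
    """Per-time-point features with class labels; baseline samples carry label -1."""

    features: np.ndarray  # (N, C) rows of the retained time points
    labels: np.ndarray  # (N,) class index, -1 = excluded (baseline)
    trial_ids: np.ndarray  # (N,) index of the schedule segment each sample came from
    class_names: list[str]
    fs: float

    def counts(self) -> dict[str, int]:
        out = {BASELINE: int(np.sum(self.labels == -1))}
        for k, name in enumerate(self.class_names):
            out[name] = int(np.sum(self.labels == k))
        return out

    def labeled_indices(self) -> np.ndarray:
        return np.nonzero(self.labels >= 0)[0]


def mbll_convert(absorbance: AbsorbanceSeries, extinction: ExtinctionTable | None = None) -> HemoglobinSeries:
    """Invert the modified Beer-Lambert law per time point and channel."""
    ext = extinction or ExtinctionTable.default(absorbance.wavelengths)
    E = ext.matrix
    cond = ext.condition_number()
    if not np.isfinite(cond):
        raise ValueError("extinction matrix is singular")
    if cond > 1e6:
        warnings.warn(
            f"extinction matrix is ill-conditioned (cond={cond:.3g}); concentrations may be unstable",
            RuntimeWarning,
        )
    ld = absorbance.source_detector_distance_cm * absorbance.dpf
    if ld <= 0:
        raise ValueError("path length l*d must be positive")
    Einv = np.linalg.inv(E)
    # (T, C, 2) @ (2, 2) -> per-sample [dHbO, dHbR]
    conc = absorbance.delta_od @ Einv.T / ld
    return HemoglobinSeries(
        hbo=conc[:, :, 0],
        hbr=conc[:, :, 1],
        fs=absorbance.fs,
        channel_names=list(absorbance.channel_names),
    )


def inverse_mbll(
    hemo: HemoglobinSeries,
    extinction: ExtinctionTable | None = None,
    source_detector_distance_cm: float = 3.0,
    dpf: float = 6.0,
    wavelengths: tuple[float, float] = (760.0, 850.0),
) -> AbsorbanceSeries:
    """Exact algebraic inverse of :func:`mbll_convert` (concentrations to absorbance)."""
    ext = extinction or ExtinctionTable.default(wavelengths)
    cond = ext.condition_number()
    if not np.isfinite(cond):
        raise ValueError("extinction matrix is singular")
    if cond > 1e6:
        warnings.warn(
            f"extinction matrix is ill-conditioned (cond={cond:.3g})",
            RuntimeWarning,
        )
    ld = source_detector_distance_cm * dpf
    if ld <= 0:
        raise ValueError("path length l*d must be positive")
    conc = np.stack([hemo.hbo, hemo.hbr], axis=2)
    dod = conc @ ext.matrix.T * ld
    return AbsorbanceSeries(
        delta_od=dod,
        fs=hemo.fs,
        wavelengths=wavelengths,
        source_detector_distance_cm=source_detector_distance_cm,
        dpf=dpf,
        channel_names=list(hemo.channel_names),
    )


def _bandpass_array(x: np.ndarray, fs: float, low: float, high: float, order: int) -> np.ndarray:
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # the low band edge implies a long impulse response; extend the reflective
    # padding accordingly so edge transients do not leak into the record
    padlen = min(x.shape[0] - 1, int(3.0 * fs / low))
    return sps.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def bandpass_filter(
    series: HemoglobinSeries,
    low: float = 0.01,
    high: float = 0.2,
    order: int = 4,
) -> HemoglobinSeries:
    """Zero-phase Butterworth band-pass, applied forward-backward per channel.

    The 0.01-0.2 Hz default passband retains the hemodynamic response while
    suppressing drift, Mayer waves above band, respiration and cardiac
    pulsation.
    """
    if not (0 < low < high < series.fs / 2):
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    return HemoglobinSeries(
        hbo=_bandpass_array(series.hbo, series.fs, low, high, order),
        hbr=_bandpass_array(series.hbr, series.fs, low, high, order),
        fs=series.fs,
        channel_names=list(series.channel_names),
    )


def build_paradigm(
    initial_rest: float = 30.0,
    n_trials: int = 10,
    activity: float = 10.0,
    rest: float = 20.0,
    final_rest: float = 30.0,
    activity_condition: str = "activity",
    rest_condition: str = "rest",
) -> ParadigmSchedule:
    """Block design: initial baseline, ``n_trials`` x (activity + rest), final baseline.

    Defaults describe a 360 s hand-gripping run: 30 s rest, ten trials of
    10 s activity and 20 s rest, and a final 30 s rest.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    segs: list[Segment] = []
    if initial_rest > 0:
        segs.append(Segment(BASELINE, initial_rest))
    for _ in range(n_trials):
        segs.append(Segment(activity_condition, activity))
        segs.append(Segment(rest_condition, rest))
    if final_rest > 0:
        segs.append(Segment(BASELINE, final_rest))
    if not segs:
        raise ValueError("schedule would be empty")
    return ParadigmSchedule(segs)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def condition_sample_counts(schedule: ParadigmSchedule, fs: float) -> dict[str, int]:
    """Per-condition sample count: floor(total condition duration * fs)."""
    return {c: int(np.floor(d * fs)) for c, d in schedule.condition_durations().items()}


def segment_and_label(
    hemo: HemoglobinSeries,
    schedule: ParadigmSchedule,
    feature: str = "hbo",
    class_order: list[str] | None = None,
    excluded_conditions: tuple[str, ...] = (BASELINE,),
) -> LabeledDataset:
    """Assign each retained time point to its paradigm condition and class label.

    Sample counts are fixed per *condition* as ``floor(total condition
    duration x fs)`` and then apportioned over that condition's segments by
    largest remainder; samples are consumed from the series in temporal
    order, so each segment is a half-open run of consecutive 0-based indices.
    Baseline (and any other excluded condition) keeps label -1; remaining
    conditions map to 0-based classes.  With the default two-condition
    paradigm the class order is (rest, activity), i.e. rest is the first
    class and activity the second.
    """
    totals = condition_sample_counts(schedule, hemo.fs)
    n_needed = sum(totals.values())
    if hemo.n_samples < n_needed:
        raise ValueError(
            f"series has {hemo.n_samples} samples but the schedule needs {n_needed}"
        )
    conditions = schedule.conditions()
    classed = [c for c in conditions if c not in excluded_conditions]
    if class_order is None:
        class_order = ["rest", "activity"] if set(classed) == {"rest", "activity"} else classed
    if set(class_order) != set(classed):
        raise ValueError("class_order must cover exactly the non-excluded conditions")
    class_of = {c: k for k, c in enumerate(class_order)}

    # per-segment quotas via largest remainder within each condition
    seg_counts = np.zeros(len(schedule.segments), dtype=int)
    for cond in conditions:
        idx = [j for j, s in enumerate(schedule.segments) if s.condition == cond]
        durs = np.array([schedule.segments[j].duration for j in idx])
        seg_counts[idx] = _largest_remainder(totals[cond], durs)

    feats = getattr(hemo, feature)
    labels = np.empty(n_needed, dtype=int)
    trial_ids = np.empty(n_needed, dtype=int)
    pos = 0
    for j, seg in enumerate(schedule.segments):
        n = seg_counts[j]
        labels[pos : pos + n] = class_of.get(seg.condition, -1)
        trial_ids[pos : pos + n] = j
        pos += n
    return LabeledDataset(
        features=feats[:n_needed].copy(),
        labels=labels,
        trial_ids=trial_ids,
        class_names=list(class_order),
        fs=hemo.fs,
    )


def split_dataset(
    labeled: LabeledDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int | np.random.Generator = 0,
    balance_classes: bool = True,
) -> dict[str, np.ndarray]:
    """Seeded stratified train/val/test split of the non-baseline samples.

    Classes are first equalised by randomly subsampling the majority class
    (an equal number of samples per class), then each partition draws from
    every trial segment via largest-remainder quotas, so per-partition class
    counts are balanced to within one sample and partitions are disjoint.
    Returns index arrays into ``labeled.features``.
    """
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ValueError("fractions must be three nonnegative numbers summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(labeled.class_names)
    per_class: list[np.ndarray] = [np.nonzero(labeled.labels == c)[0] for c in range(k)]
    if any(len(ix) == 0 for ix in per_class):
        raise ValueError("every class needs at least one sample")

    if balance_classes:
        n_per = min(len(ix) for ix in per_class)
        balanced = []
        for ix in per_class:
            if len(ix) > n_per:
                # subsample proportionally from each trial of the class
                trials = labeled.trial_ids[ix]
                uniq = np.unique(trials)
                take = _largest_remainder(n_per, np.array([np.sum(trials == t) for t in uniq]))
                keep = [rng.choice(ix[trials == t], size=n, replace=False) for t, n in zip(uniq, take)]
                ix = np.sort(np.concatenate(keep))
            balanced.append(ix)
        per_class = balanced

    parts: dict[str, list[np.ndarray]] = {"train": [], "val": [], "test": []}
    for ix in per_class:
        n = len(ix)
        n_train, n_val, n_test = _largest_remainder(n, np.array(fractions))
        trials = labeled.trial_ids[ix]
        uniq = np.unique(trials)
        sizes = np.array([np.sum(trials == t) for t in uniq])
        remaining = {t: rng.permutation(ix[trials == t]).tolist() for t in uniq}
        for name, want in (("test", n_test), ("val", n_val), ("train", n_train)):
            avail = np.array([len(remaining[t]) for t in uniq])
            if name == "train":
                take = avail  # everything left
            else:
                want = min(want, int(avail.sum()))
                take = np.minimum(_largest_remainder(want, np.maximum(avail, 1e-9)), avail)
                while take.sum() < want:  # redistribute any clipped shortfall
                    j = int(np.argmax(avail - take))
                    take[j] += 1
            chosen = []
            for t, m in zip(uniq, take):
                for _ in range(int(m)):
                    chosen.append(remaining[t].pop())
            parts[name].append(np.array(sorted(chosen), dtype=int))
        _ = sizes, n_train
    return {name: np.sort(np.concatenate(v)) for name, v in parts.items()}


def class_difference_ttest(labeled: LabeledDataset, feature_reduce: str = "mean") -> tuple[float, float]:
    """Two-tailed pooled two-sample t-test between the two class populations.

    Each time point is reduced to a scalar (default: mean over channels); the
    test compares the class-0 and class-1 scalar populations.
    """
    from .stats import two_sample_ttest

    if len(labeled.class_names) != 2:
        raise ValueError("class_difference_ttest requires a two-class dataset")
    if feature_reduce != "mean":
        raise ValueError("only 'mean' channel reduction is supported")
    x = labeled.features.mean(axis=1)
    a = x[labeled.labels == 1]  # activity
    b = x[labeled.labels == 0]  # rest
    return two_sample_ttest(a, b)


def make_windows(
    labeled: LabeledDataset,
    indices: np.ndarray,
    window_length: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Causal windows of ``window_length`` time points ending at each labeled sample.

    Windows never reach across a segment boundary: positions before the
    sample's own segment start are filled by replicating the segment's first
    sample.  Returns (X (N, W, C), y (N,)).
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    feats = labeled.features
    starts: dict[int, int] = {}
    for i, t in enumerate(labeled.trial_ids):
        starts.setdefault(int(t), i)
    N = len(indices)
    W = window_length
    X = np.empty((N, W, feats.shape[1]))
    y = np.empty(N, dtype=int)
    for n, i in enumerate(indices):
        s0 = starts[int(labeled.trial_ids[i])]
        lo = i - W + 1
        if lo >= s0:
            X[n] = feats[lo : i + 1]
        else:
            pad = s0 - lo
            X[n, :pad] = feats[s0]
            X[n, pad:] = feats[s0 : i + 1]
        y[n] = labeled.labels[i]
    return X, y
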