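"""Synthetic block-design fNIRS data with known ground truth.

A subject is simulated by convolving each task condition's boxcar with a
canonical double-gamma hemodynamic response function (HRF), projecting the
response onto a subset of active channels, and adding physiological noise
(white noise, Mayer waves, respiration, cardiac pulsation, linear drift).
dHbR is generated as a negatively scaled copy of dHbO, reflecting the
typical anticorrelation of the two chromophores.  Datasets can be emitted
either as hemoglobin concentrations or, through the inverse Beer-Lambert
map, as raw-style two-wavelength absorbance so the full conversion path is
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocessing import (
    DEFAULT_FS,
    AbsorbanceSeries,
    ExtinctionTable,
    HemoglobinSeries,
    LabeledDataset,
    ParadigmSchedule,
    Segment,
    build_paradigm,
    inverse_mbll,
    segment_and_label,
)

__all__ = [
    "HRFParams",
    "NoiseParams",
    "SyntheticSubjectConfig",
    "canonical_hrf",
    "generate_subject",
    "generate_cohort",
    "multiclass_paradigm",
]


@dataclass
class HRFParams:
    """Double-gamma HRF: positive peak minus a delayed undershoot.

    Delays/dispersions in seconds; ``amplitude`` is the kernel peak in uM.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("HRF delays must be positive")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("HRF dispersions must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("HRF amplitude must be finite")


@dataclass
class NoiseParams:
    """Additive noise model: white noise, sinusoidal physiology, linear drift.

    Sinusoids are (frequency Hz, amplitude uM) pairs; defaults are Mayer
    waves (~0.1 Hz), respiration (~0.3 Hz) and cardiac pulsation (~1.0 Hz).
    """

    white_sd: float = 0.1
    sinusoids: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.1, 0.1), (0.3, 0.1), (1.0, 0.1)]
    )
    drift_slope: float = 0.001  # uM per second

    def __post_init__(self) -> None:
        if self.white_sd < 0 or any(a < 0 for _, a in self.sinusoids):
            raise ValueError("noise amplitudes must be nonnegative")


def default_channel_weights(n_channels: int, conditions: list[str]) -> dict[str, np.ndarray]:
    """Fixed activation topography: each task condition excites a block of channels.

    Condition ``j`` activates channels ``[j*4, j*4+8)`` (wrapping) with
    weights tapering from 1.0 to 0.5, loosely mimicking a focal cortical
    response spread over neighbouring optode channels.
    """
    weights: dict[str, np.ndarray] = {}
    n_active = min(8, n_channels)
    taper = np.linspace(1.0, 0.5, n_active)
    for j, cond in enumerate(conditions):
        w = np.zeros(n_channels)
        for i in range(n_active):
            w[(j * 4 + i) % n_channels] = taper[i]
        weights[cond] = w
    return weights


@dataclass
class SyntheticSubjectConfig:
    """Everything needed to simulate one subject reproducibly."""

    paradigm: ParadigmSchedule = field(default_factory=build_paradigm)
    fs: float = DEFAULT_FS
    n_channels: int = 20
    hrf: HRFParams = field(default_factory=HRFParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    channel_weights: dict[str, np.ndarray] | None = None  # per task condition
    hbr_ratio: float = -1.0 / 3.0
    seed: int = 0
    emit_mode: str = "hemoglobin"  # or "absorbance"
    task_conditions: list[str] | None = None

    def resolved_task_conditions(self) -> list[str]:
        if self.task_conditions is not None:
            return list(self.task_conditions)
        conds = [c for c in self.paradigm.conditions() if c not in ("baseline", "rest")]
        return conds

    def resolved_weights(self) -> dict[str, np.ndarray]:
        conds = self.resolved_task_conditions()
        if not conds:
            raise ValueError("paradigm has no task condition")
        w = self.channel_weights or default_channel_weights(self.n_channels, conds)
        for c in conds:
            if c not in w:
                raise ValueError(f"missing channel weights for condition {c!r}")
            if len(w[c]) != self.n_channels or not np.any(w[c] != 0):
                raise ValueError(f"condition {c!r} needs at least one active channel")
        return {c: np.asarray(w[c], dtype=float) for c in conds}


def canonical_hrf(params: HRFParams, fs: float, duration: float = 32.0) -> np.ndarray:
    """Sample the double-gamma kernel at ``fs`` over ``duration`` seconds.

    Each gamma lobe is parameterised so its mode sits at the configured
    delay; the kernel is rescaled so its peak equals ``amplitude``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    t = np.arange(0.0, duration, 1.0 / fs)

    def lobe(delay: float, disp: float) -> np.ndarray:
        shape = delay / disp + 1.0  # mode = (shape - 1) * scale = delay
        from scipy.stats import gamma as gamma_dist

        return gamma_dist.pdf(t, a=shape, scale=disp)

    h = lobe(params.peak_delay, params.peak_dispersion) - params.undershoot_ratio * lobe(
        params.undershoot_delay, params.undershoot_dispersion
    )
    peak = np.max(np.abs(h))
    if peak == 0 or params.amplitude == 0:
        return np.zeros_like(t)
    return h * (params.amplitude / np.max(h))


def _condition_boxcar(schedule: ParadigmSchedule, fs: float, condition: str, n: int) -> np.ndarray:
    box = np.zeros(n)
    t0 = 0.0
    for seg in schedule.segments:
        if seg.condition == condition:
            a = int(np.floor(t0 * fs))
            b = min(int(np.floor((t0 + seg.duration) * fs)), n)
            box[a:b] = 1.0
        t0 += seg.duration
    return box


def generate_subject(
    config: SyntheticSubjectConfig,
) -> tuple[HemoglobinSeries | AbsorbanceSeries, LabeledDataset]:
    """Simulate one subject; returns the emitted series and its ground-truth labels.

    Ground truth comes from running the paradigm segmentation on the emitted
    series, so generator labels and pipeline labels agree by construction.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(np.floor(config.paradigm.total_duration * fs))
    t = np.arange(n) / fs
    C = config.n_channels
    weights = config.resolved_weights()

    kernel = canonical_hrf(config.hrf, fs)
    hbo = np.zeros((n, C))
    for cond, w in weights.items():
        box = _condition_boxcar(config.paradigm, fs, cond, n)
        response = np.convolve(box, kernel)[:n] / fs
        # normalise the block response so a sustained block reaches ~amplitude
        norm = np.sum(kernel) / fs / max(config.hrf.amplitude, 1e-12) if np.any(kernel) else 1.0
        if norm != 0:
            response = response / norm
        hbo += np.outer(response, w)

    noise = np.zeros((n, C))
    if config.noise.white_sd > 0:
        noise += rng.normal(0.0, config.noise.white_sd, size=(n, C))
    for freq, amp in config.noise.sinusoids:
        if amp > 0:
            phases = rng.uniform(0, 2 * np.pi, size=C)
            noise += amp * np.sin(2 * np.pi * freq * t[:, None] + phases[None, :])
    if config.noise.drift_slope != 0:
        slopes = config.noise.drift_slope * rng.uniform(0.5, 1.5, size=C)
        noise += t[:, None] * slopes[None, :]

    hbo_noisy = hbo + noise
    hbr = config.hbr_ratio * hbo + 0.3 * (
        rng.normal(0.0, config.noise.white_sd, size=(n, C)) if config.noise.white_sd > 0 else 0.0
    )
    hemo = HemoglobinSeries(hbo=hbo_noisy, hbr=hbr, fs=fs)

    excluded = ("baseline",) if len(weights) == 1 else ("baseline", "rest")
    truth = segment_and_label(hemo, config.paradigm, excluded_conditions=excluded)

    if config.emit_mode == "hemoglobin":
        return hemo, truth
    if config.emit_mode == "absorbance":
        return inverse_mbll(hemo), truth
    raise ValueError(f"unknown emit_mode {config.emit_mode!r}")


def multiclass_paradigm(
    n_classes: int = 3,
    trials_per_class: int = 25,
    activity: float = 10.0,
    rest: float = 20.0,
    initial_rest: float = 30.0,
    final_rest: float = 30.0,
) -> ParadigmSchedule:
    """Round-robin multi-task block design (task1..taskK), equal trials per class."""
    if n_classes < 2 or trials_per_class < 1:
        raise ValueError("need >= 2 classes and >= 1 trial per class")
    segs = [Segment("baseline", initial_rest)]
    for _ in range(trials_per_class):
        for j in range(n_classes):
            segs.append(Segment(f"task{j + 1}", activity))
            segs.append(Segment("rest", rest))
    segs.append(Segment("baseline", final_rest))
    return ParadigmSchedule(segs)


def generate_cohort(
    n_subjects: int,
    config: SyntheticSubjectConfig | None = None,
    master_seed: int = 0,
    jitter_sigma: float = 0.2,
) -> list[tuple[HemoglobinSeries | AbsorbanceSeries, LabeledDataset]]:
    """Simulate a cohort with deterministic per-subject seeds and log-normal
    inter-subject variability (sigma=0.2) on HRF amplitude and white-noise SD."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    template = config or SyntheticSubjectConfig()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects)
    out = []
    for child in children:
        seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        jrng = np.random.default_rng(seed + 1)
        amp = template.hrf.amplitude * float(jrng.lognormal(0.0, jitter_sigma))
        wsd = template.noise.white_sd * float(jrng.lognormal(0.0, jitter_sigma))
        cfg = replace(
            template,
            hrf=replace(template.hrf, amplitude=amp),
            noise=replace(template.noise, white_sd=wsd),
            seed=seed,
        )
        out.append(generate_subject(cfg))
    return out
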