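"""Tests for Beer-Lambert conversion, filtering, segmentation and splitting."""

import numpy as np
import pytest

from icgn_bci.preprocessing import (
    DEFAULT_FS,
    AbsorbanceSeries,
    ExtinctionTable,
    HemoglobinSeries,
    bandpass_filter,
    build_paradigm,
    class_difference_ttest,
    condition_sample_counts,
    inverse_mbll,
    make_windows,
    mbll_convert,
    segment_and_label,
    split_dataset,
)

IDENTITY_EXT = ExtinctionTable(1.0, 0.0, 0.0, 1.0)


def _abs_series(dod, **kw):
    kw.setdefault("source_detector_distance_cm", 1.0)
    kw.setdefault("dpf", 1.0)
    return AbsorbanceSeries(delta_od=dod, **kw)


class TestMBLL:
    def test_zero_absorbance_gives_zero_concentration(self):
        h = mbll_convert(_abs_series(np.zeros((5, 3, 2))), IDENTITY_EXT)
        assert np.all(h.hbo == 0) and np.all(h.hbr == 0)

    def test_identity_extinction_passes_through(self, rng):
        dod = rng.normal(size=(6, 2, 2))
        h = mbll_convert(_abs_series(dod), IDENTITY_EXT)
        assert np.allclose(h.hbo, dod[:, :, 0])
        assert np.allclose(h.hbr, dod[:, :, 1])

    def test_two_by_two_inverse_by_hand(self):
        # E = [[2,1],[1,2]], dA = (3,3)  ->  E^-1 dA = (1,1)
        ext = ExtinctionTable(2.0, 1.0, 1.0, 2.0)
        dod = np.full((1, 1, 2), 3.0)
        h = mbll_convert(_abs_series(dod), ext)
        assert np.allclose(h.hbo, 1.0) and np.allclose(h.hbr, 1.0)

    def test_linearity(self, rng):
        ext = ExtinctionTable(2.0, 1.0, 0.5, 2.0)
        x = rng.normal(size=(4, 2, 2))
        y = rng.normal(size=(4, 2, 2))
        fa = mbll_convert(_abs_series(2 * x + 3 * y), ext)
        fx = mbll_convert(_abs_series(x), ext)
        fy = mbll_convert(_abs_series(y), ext)
        assert np.allclose(fa.hbo, 2 * fx.hbo + 3 * fy.hbo)
        assert np.allclose(fa.hbr, 2 * fx.hbr + 3 * fy.hbr)

    def test_round_trip_identity(self, rng):
        hemo = HemoglobinSeries(hbo=rng.normal(size=(50, 4)), hbr=rng.normal(size=(50, 4)))
        back = mbll_convert(inverse_mbll(hemo))
        assert np.max(np.abs(back.hbo - hemo.hbo)) < 1e-10
        assert np.max(np.abs(back.hbr - hemo.hbr)) < 1e-10

    def test_ill_conditioned_extinction_warns_but_returns(self, rng):
        ext = ExtinctionTable(1.0, 1.0, 1.0, 1.0 + 1e-8)
        hemo = HemoglobinSeries(hbo=rng.normal(size=(3, 1)), hbr=rng.normal(size=(3, 1)))
        with pytest.warns(RuntimeWarning):
            out = inverse_mbll(hemo, ext)
        assert out.delta_od.shape == (3, 1, 2)

    def test_singular_extinction_raises(self):
        ext = ExtinctionTable(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            mbll_convert(_abs_series(np.zeros((2, 1, 2))), ext)


class TestBandpass:
    """Responses checked in steady state: a 30 s settle interval is trimmed at
    each record edge before computing RMS, since the 0.01 Hz band edge implies
    a long transient."""

    FS = DEFAULT_FS

    def _rms_ratio(self, freq, duration=360.0):
        t = np.arange(0, duration, 1 / self.FS)
        x = np.sin(2 * np.pi * freq * t)[:, None]
        y = bandpass_filter(HemoglobinSeries(hbo=x, hbr=x, fs=self.FS)).hbo[:, 0]
        k = int(30 * self.FS)
        return np.sqrt(np.mean(y[k:-k] ** 2)) / np.sqrt(np.mean(x[k:-k, 0] ** 2))

    def test_stopband_1hz_attenuated(self):
        assert self._rms_ratio(1.0) < 0.05

    def test_passband_0p05hz_preserved(self):
        assert 0.8 <= self._rms_ratio(0.05) <= 1.1

    def test_dc_removed(self):
        x = np.ones((3662, 1))
        y = bandpass_filter(HemoglobinSeries(hbo=x, hbr=x, fs=self.FS)).hbo[:, 0]
        k = int(30 * self.FS)
        assert abs(np.mean(y[k:-k])) < 0.01

    def test_zero_phase_no_lag(self):
        t = np.arange(0, 360, 1 / self.FS)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass_filter(HemoglobinSeries(hbo=x[:, None], hbr=x[:, None], fs=self.FS)).hbo[:, 0]
        c = np.correlate(y, x, "full")
        assert abs(int(np.argmax(c)) - (len(x) - 1)) <= 1

    def test_invalid_band_edges_raise(self):
        h = HemoglobinSeries(hbo=np.zeros((10, 1)), hbr=np.zeros((10, 1)), fs=10.0)
        with pytest.raises(ValueError):
            bandpass_filter(h, low=0.2, high=0.1)
        with pytest.raises(ValueError):
            bandpass_filter(h, low=0.01, high=6.0)


class TestParadigm:
    def test_default_schedule_totals_360s(self):
        assert build_paradigm().total_duration == 360.0

    def test_no_trials_gives_two_baselines(self):
        sch = build_paradigm(n_trials=0)
        assert sch.total_duration == 60.0
        assert [s.condition for s in sch.segments] == ["baseline", "baseline"]

    def test_custom_arithmetic(self):
        sch = build_paradigm(initial_rest=10, n_trials=2, activity=5, rest=5, final_rest=10)
        assert sch.total_duration == 40.0


class TestSegmentation:
    def test_benchmark_counts_at_native_sampling_rate(self, default_paradigm):
        counts = condition_sample_counts(default_paradigm, DEFAULT_FS)
        assert counts == {"baseline": 610, "activity": 1017, "rest": 2034}
        assert sum(counts.values()) == 3661

    def test_integer_rate_counts_equal_durations(self):
        sch = build_paradigm()
        counts = condition_sample_counts(sch, 1.0)
        assert counts == {"baseline": 60, "activity": 100, "rest": 200}

    def test_fractional_rate_floor_rule(self):
        sch = build_paradigm(initial_rest=0, n_trials=1, activity=3, rest=2, final_rest=0)
        counts = condition_sample_counts(sch, 2.5)
        assert counts == {"activity": 7, "rest": 5}

    def test_labels_follow_schedule_order_and_counts(self, rng):
        sch = build_paradigm()
        n = int(np.floor(360 * DEFAULT_FS))
        hemo = HemoglobinSeries(hbo=rng.normal(size=(n, 2)), hbr=rng.normal(size=(n, 2)))
        lab = segment_and_label(hemo, sch)
        assert lab.counts() == {"baseline": 610, "rest": 2034, "activity": 1017}
        # first samples are baseline, then the first activity trial
        assert lab.labels[0] == -1
        first_act = np.nonzero(lab.labels == 1)[0][0]
        assert lab.trial_ids[first_act] == 1

    def test_series_shorter_than_schedule_raises(self):
        sch = build_paradigm()
        hemo = HemoglobinSeries(hbo=np.zeros((100, 1)), hbr=np.zeros((100, 1)))
        with pytest.raises(ValueError):
            segment_and_label(hemo, sch)


class TestSplit:
    @staticmethod
    def _toy_labeled(n_per_class=50):
        from icgn_bci.preprocessing import LabeledDataset

        labels = np.array([0, 1] * n_per_class)
        trials = np.tile([0, 1], n_per_class)
        return LabeledDataset(
            features=np.arange(2 * n_per_class, dtype=float)[:, None],
            labels=labels,
            trial_ids=trials,
            class_names=["rest", "activity"],
            fs=1.0,
        )

    def test_balanced_80_10_10(self):
        lab = self._toy_labeled(50)
        parts = split_dataset(lab, seed=0)
        sizes = {k: len(v) for k, v in parts.items()}
        assert sizes == {"train": 80, "val": 10, "test": 10}
        for idx in parts.values():
            counts = np.bincount(lab.labels[idx], minlength=2)
            assert abs(counts[0] - counts[1]) <= 1

    def test_same_seed_identical_partitions(self):
        lab = self._toy_labeled(50)
        a = split_dataset(lab, seed=5)
        b = split_dataset(lab, seed=5)
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_partitions_disjoint_and_exhaustive_over_balanced_set(self, labeled_subject):
        parts = split_dataset(labeled_subject, seed=1)
        allidx = np.concatenate(list(parts.values()))
        assert len(allidx) == len(set(allidx))
        # balanced subsample: 2 x minority class size
        counts = labeled_subject.counts()
        assert len(allidx) == 2 * min(counts["activity"], counts["rest"])
        # every partition is class balanced to within one
        for idx in parts.values():
            c = np.bincount(labeled_subject.labels[idx], minlength=2)
            assert abs(int(c[0]) - int(c[1])) <= 1
        # test partition draws from every trial of the paradigm
        test_trials = set(labeled_subject.trial_ids[parts["test"]])
        all_trials = set(labeled_subject.trial_ids[labeled_subject.labeled_indices()])
        assert test_trials == all_trials

    def test_bad_fractions_raise(self):
        lab = self._toy_labeled(10)
        with pytest.raises(ValueError):
            split_dataset(lab, fractions=(0.5, 0.2, 0.2))


class TestWindows:
    def test_window_replicates_segment_start(self):
        lab = TestSplit._toy_labeled(10)
        # all trial 0 samples are the even indices; first sample of trial 0 is row 0
        X, y = make_windows(lab, np.array([0]), window_length=4)
        assert X.shape == (1, 4, 1)
        assert np.allclose(X[0, :, 0], lab.features[0, 0])

    def test_window_contents_are_causal(self, labeled_subject):
        idx = labeled_subject.labeled_indices()[:5]
        X, y = make_windows(labeled_subject, idx, window_length=3)
        for n, i in enumerate(idx):
            assert np.allclose(X[n, -1], labeled_subject.features[i])


class TestClassTTest:
    def test_identical_classes_give_zero_t(self):
        from icgn_bci.preprocessing import LabeledDataset

        feats = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), 2)[:, None]
        lab = LabeledDataset(
            features=feats,
            labels=np.array([0] * 4 + [1] * 4),
            trial_ids=np.zeros(8, dtype=int),
            class_names=["rest", "activity"],
            fs=1.0,
        )
        t, p = class_difference_ttest(lab)
        assert t == 0.0 and p == 1.0

    def test_separated_classes_significant(self, rng):
        from icgn_bci.preprocessing import LabeledDataset

        feats = np.concatenate([np.zeros(4), np.ones(4)])[:, None] + rng.normal(0, 1e-3, (8, 1))
        lab = LabeledDataset(
            features=feats,
            labels=np.array([0] * 4 + [1] * 4),
            trial_ids=np.zeros(8, dtype=int),
            class_names=["rest", "activity"],
            fs=1.0,
        )
        t, p = class_difference_ttest(lab)
        assert p < 0.001
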