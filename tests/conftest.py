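import numpy as np
import pytest

from icgn_bci import synthetic
from icgn_bci.preprocessing import HemoglobinSeries, bandpass_filter, build_paradigm, segment_and_label


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_paradigm():
    return build_paradigm()


@pytest.fixture(scope="session")
def high_snr_subject():
    """One high-SNR synthetic subject (white SD = 10% of HRF amplitude)."""
    cfg = synthetic.SyntheticSubjectConfig(seed=11)
    series, truth = synthetic.generate_subject(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def labeled_subject(high_snr_subject):
    cfg, series, _ = high_snr_subject
    filtered = bandpass_filter(series)
    return segment_and_label(filtered, cfg.paradigm)
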