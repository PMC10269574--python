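import numpy as np
import pytest

from aphasia_eeg import build_schedule, default_schedule


def direct_dft_power(x, fs):
    """Brute-force O(n²) one-sided power spectrum, independent of numpy.fft.

    Computes the DFT sums explicitly from cosines and sines and applies
    the same one-sided Parseval scaling the package promises, so it can
    serve as an oracle for the FFT path.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    n_bins = n // 2 + 1
    power = np.zeros(n_bins)
    t = np.arange(n)
    for k in range(n_bins):
        re = float(np.sum(x * np.cos(2 * np.pi * k * t / n)))
        im = float(np.sum(x * np.sin(2 * np.pi * k * t / n)))
        p = (re * re + im * im) / n ** 2
        if 0 < k and not (n % 2 == 0 and k == n // 2):
            p *= 2.0
        power[k] = p
    freqs = np.arange(n_bins) * fs / n
    return freqs, power


@pytest.fixture(scope="session")
def paper_schedule():
    """The published paradigm: 40-s baseline, 240-s task, 5-s sentences."""
    return default_schedule()


@pytest.fixture
def tiny_schedule():
    """A 40-s task (two 2-sentence blocks per cycle) for fast pipeline tests."""
    return build_schedule(sentence_duration_s=5, sentences_per_block=2,
                          task_duration_s=40, baseline_segments=[])
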