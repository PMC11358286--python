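import numpy as np
import pytest

from synchrolab import generate_sequence


@pytest.fixture
def iso_seq():
    """Standard 60-click isochronous sequence at 1250 ms."""
    return generate_sequence(60, 1250, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def oracle_coherence(epochs, band=(12.0, 30.0), n_cycles=1.0, freq_step=2.0):
    """Brute-force coherence computed directly from the definition.

    Explicit loops and ``numpy.convolve`` -- no code shared with the
    implementation beyond the Morlet kernels themselves.  Returns
    (per_epoch, across_epoch) arrays over all channel pairs in index
    order.
    """
    from mne.time_frequency import morlet

    freqs = np.arange(band[0], band[1] + freq_step / 2, freq_step)
    kernels = morlet(epochs.sfreq, freqs, n_cycles=n_cycles, zero_mean=False)
    n_ch, n_ep, n_t = epochs.data.shape
    pairs = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
    sxy = {p: np.zeros(n_ep, complex) for p in pairs}
    sxx = np.zeros((n_ch, n_ep))
    for kernel in kernels:
        half = len(kernel) // 2
        W = np.empty((n_ch, n_ep, n_t - 2 * half), complex)
        for c in range(n_ch):
            for e in range(n_ep):
                conv = np.convolve(epochs.data[c, e], kernel, mode="same")
                W[c, e] = conv[half : n_t - half]
        for (i, j) in pairs:
            for e in range(n_ep):
                sxy[(i, j)][e] += np.sum(W[i, e] * np.conj(W[j, e]))
        for c in range(n_ch):
            for e in range(n_ep):
                sxx[c, e] += np.sum(np.abs(W[c, e]) ** 2)
    per_epoch = np.array(
        [np.abs(sxy[p]) / np.sqrt(sxx[p[0]] * sxx[p[1]]) for p in pairs]
    )
    overall = np.array(
        [
            np.abs(sxy[p].sum()) / np.sqrt(sxx[p[0]].sum() * sxx[p[1]].sum())
            for p in pairs
        ]
    )
    return per_epoch, overall
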