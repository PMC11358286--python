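"""Tap-locked EEG beta-band coherence with resting-state subtraction.

The analysis epochs continuous EEG around each tap, computes time-resolved
Morlet-wavelet cross- and auto-spectra in the beta band (12-30 Hz), and
forms the magnitude-squared-free coherence

    C_xy = |E[S_xy]| / sqrt(E[S_xx] * E[S_yy]),

where S_xy(f, t) = W_x(f, t) * conj(W_y(f, t)) and the expectation runs
over time samples and band frequencies (per-epoch coherence) or jointly
over epochs, time and band (across-epoch coherence).  Rest coherence from
30-s eyes-open segments, cut into epochs of the task length, is subtracted
per link; the difference is zeroed wherever a two-sample Kolmogorov-
Smirnov test cannot distinguish the task and rest per-epoch distributions
(p >= 0.01).  Masked differences are finally averaged within three
fronto-central link groups (intrahemispheric contralateral, midline,
interhemispheric).

Wavelet kernels come from :func:`mne.time_frequency.morlet`; time samples
whose kernel support overhangs the epoch edge are excluded from the
expectation.  Coherence is invariant to per-channel amplitude scaling, so
no unit conversion is needed beyond consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

DEFAULT_SFREQ = 250.0
DEFAULT_BAND = (12.0, 30.0)
DEFAULT_FREQ_STEP = 2.0
DEFAULT_N_CYCLES = 1.0
DEFAULT_ALPHA = 0.01

#: ms relative to tap onset
TASK_WINDOW = (-100.0, 500.0)
BASELINE_WINDOW = (-500.0, -300.0)
EXTENDED_WINDOW = (-500.0, 500.0)

#: Channels excluded from connectivity analysis (posterior/occipital).
EXCLUDED_CHANNELS = ("PO7", "PO3", "PO4", "PO8", "Oz")

#: Fronto-central network link groups.
DEFAULT_NETWORKS: dict[str, tuple[tuple[str, str], ...]] = {
    "intrahemispheric": (("Fp1", "F3"), ("F3", "C5"), ("C5", "C1")),
    "midline": (("Fz", "Cz"), ("Fz", "Pz")),
    "interhemispheric": (("Fp1", "Fp2"), ("F3", "F4"), ("C5", "C6")),
}


@dataclass(frozen=True)
class EpochSet:
    """Equal-length EEG epochs: ``data`` is (channels, epochs, samples) in µV."""

    data: np.ndarray
    sfreq: float
    window: tuple[float, float]  # ms relative to the locking event
    channel_labels: tuple[str, ...]
    kind: str  # "task" | "rest"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("epoch data must be (channels, epochs, samples)")
        if data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels must match first axis of data")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def connectivity_view(self) -> "EpochSet":
        """Drop the channels excluded from connectivity analysis."""
        keep = [i for i, ch in enumerate(self.channel_labels)
                if ch not in EXCLUDED_CHANNELS]
        return EpochSet(
            data=self.data[keep],
            sfreq=self.sfreq,
            window=self.window,
            channel_labels=tuple(self.channel_labels[i] for i in keep),
            kind=self.kind,
        )


def _ms_to_samples(ms: float, sfreq: float) -> int:
    return int(round(ms * sfreq / 1000.0))


def epoch_task(
    data: np.ndarray,
    sfreq: float,
    tap_times_ms: np.ndarray,
    channel_labels: tuple[str, ...] | list[str],
    window: tuple[float, float] = TASK_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> EpochSet:
    """Cut baseline-corrected task epochs around tap onsets.

    Extended cuts spanning the union of ``baseline_window`` and ``window``
    are made first, the per-channel mean over the baseline window is
    subtracted, then epochs are cropped to ``window``.  Taps without
    enough surrounding data are dropped (with a warning count).

    At the 250 Hz default, the −100..+500 ms window yields epochs of
    exactly 150 samples.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("continuous data must be (channels, samples)")
    ext_lo = min(baseline_window[0], window[0])
    ext_hi = max(baseline_window[1], window[1])
    pre = _ms_to_samples(-ext_lo, sfreq)
    post = _ms_to_samples(ext_hi, sfreq)
    b0 = _ms_to_samples(baseline_window[0] - ext_lo, sfreq)
    b1 = _ms_to_samples(baseline_window[1] - ext_lo, sfreq)
    c0 = _ms_to_samples(window[0] - ext_lo, sfreq)
    c1 = _ms_to_samples(window[1] - ext_lo, sfreq)
    n_samples = data.shape[1]
    epochs = []
    n_dropped = 0
    for tap in np.asarray(tap_times_ms, dtype=float):
        center = _ms_to_samples(tap, sfreq)
        lo, hi = center - pre, center + post
        if lo < 0 or hi > n_samples:
            n_dropped += 1
            continue
        cut = data[:, lo:hi]
        baseline = cut[:, b0:b1].mean(axis=1, keepdims=True)
        epochs.append((cut - baseline)[:, c0:c1])
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} taps with insufficient data around them",
                      stacklevel=2)
    if not epochs:
        raise ValueError("no tap produced a complete epoch")
    return EpochSet(
        data=np.stack(epochs, axis=1),
        sfreq=sfreq,
        window=window,
        channel_labels=tuple(channel_labels),
        kind="task",
    )


def epoch_rest(
    data: np.ndarray,
    sfreq: float,
    epoch_length_ms: float = TASK_WINDOW[1] - TASK_WINDOW[0],
    channel_labels: tuple[str, ...] | list[str] = (),
) -> EpochSet:
    """Cut a resting recording into consecutive non-overlapping epochs.

    No baseline subtraction is applied (there is no locking event); any
    remainder shorter than one epoch is discarded.  A 30-s recording at
    600 ms epochs yields 50 epochs.
    """
    data = np.asarray(data, dtype=float)
    n_per = _ms_to_samples(epoch_length_ms, sfreq)
    n_epochs = data.shape[1] // n_per
    if n_epochs == 0:
        raise ValueError(
            f"recording ({data.shape[1]} samples) shorter than one epoch ({n_per})"
        )
    cut = data[:, : n_epochs * n_per].reshape(data.shape[0], n_epochs, n_per)
    return EpochSet(
        data=cut,
        sfreq=sfreq,
        window=(0.0, epoch_length_ms),
        channel_labels=tuple(channel_labels) or tuple(
            f"ch{i}" for i in range(data.shape[0])
        ),
        kind="rest",
    )


# ---------------------------------------------------------------------------
# wavelet coherence


def band_frequencies(
    band: tuple[float, float] = DEFAULT_BAND, step: float = DEFAULT_FREQ_STEP
) -> np.ndarray:
    """Center frequencies spanning the band (default 12:2:30 Hz, inclusive)."""
    lo, hi = band
    return np.arange(lo, hi + step / 2, step)


def all_pairs(channel_labels: tuple[str, ...]) -> list[tuple[str, str]]:
    return [
        (channel_labels[i], channel_labels[j])
        for i in range(len(channel_labels))
        for j in range(i + 1, len(channel_labels))
    ]


@dataclass
class CoherenceResult:
    """Per-link coherence: per-epoch values plus the across-epoch estimate.

    ``per_epoch[l, e]`` is the coherence of link l within epoch e (the
    expectation over time and band inside that epoch); ``overall[l]`` pools
    epochs, time and band in one expectation.  Links with a zero-power
    channel are NaN and listed in ``flagged``.
    """

    links: list[tuple[str, str]]
    per_epoch: np.ndarray
    overall: np.ndarray
    band: tuple[float, float]
    kind: str
    flagged: list[tuple[str, str]] = field(default_factory=list)

    def link_index(self, a: str, b: str) -> int:
        for i, (x, y) in enumerate(self.links):
            if {x, y} == {a, b}:
                return i
        raise KeyError(f"link {a}-{b} not present")


def _morlet_kernels(sfreq: float, freqs: np.ndarray, n_cycles: float) -> list[np.ndarray]:
    from mne.time_frequency import morlet

    return morlet(sfreq, freqs, n_cycles=n_cycles, zero_mean=False)


def wavelet_coherence(
    epochs: EpochSet,
    band: tuple[float, float] = DEFAULT_BAND,
    n_cycles: float = DEFAULT_N_CYCLES,
    freq_step: float = DEFAULT_FREQ_STEP,
    links: list[tuple[str, str]] | None = None,
) -> CoherenceResult:
    """Morlet-wavelet coherence for channel pairs of an epoch set.

    For each link and frequency, the analytic signals W_x, W_y are obtained
    by convolution with a complex Morlet kernel ('same' alignment); time
    samples whose kernel support overhangs the epoch are excluded.  The
    cross-spectrum S_xy = W_x conj(W_y) and auto-spectra are then averaged
    -- over time and band within each epoch (``per_epoch``), and jointly
    over epochs, time and band (``overall``).

    Parameters
    ----------
    links
        Channel pairs to evaluate; default: all pairs of the epoch set's
        channels (after connectivity exclusions, if the caller applied
        them).
    """
    if epochs.n_epochs < 2:
        raise ValueError("need at least 2 epochs for coherence")
    nyq = epochs.sfreq / 2
    if not 0 < band[0] < band[1] < nyq:
        raise ValueError(f"band {band} must lie within (0, {nyq}) Hz")
    labels = epochs.channel_labels
    if links is None:
        links = all_pairs(labels)
    idx = {ch: i for i, ch in enumerate(labels)}
    for a, b in links:
        if a not in idx or b not in idx:
            raise ValueError(f"link {a}-{b} uses a channel not in the epoch set")
    ia = np.array([idx[a] for a, _ in links])
    ib = np.array([idx[b] for _, b in links])

    freqs = band_frequencies(band, freq_step)
    kernels = _morlet_kernels(epochs.sfreq, freqs, n_cycles)
    n_ch, n_ep, n_t = epochs.data.shape
    used_ch = sorted(set(ia) | set(ib))

    num = np.zeros((len(links), n_ep), dtype=complex)  # sum of S_xy
    auto = np.zeros((n_ch, n_ep), dtype=float)  # sum of S_xx
    counts = 0
    for kernel in kernels:
        half = len(kernel) // 2
        if 2 * half >= n_t:
            raise ValueError(
                f"wavelet kernel ({len(kernel)} samples) does not fit the epoch"
            )
        # full-support samples under 'same' alignment
        t0, t1 = half, n_t - half
        W = np.empty((n_ch, n_ep, t1 - t0), dtype=complex)
        for c in used_ch:
            conv = sps.fftconvolve(
                epochs.data[c], kernel[np.newaxis, :], mode="same", axes=1
            )
            W[c] = conv[:, t0:t1]
        num += np.sum(W[ia] * np.conj(W[ib]), axis=-1)
        auto[used_ch] += np.sum(np.abs(W[used_ch]) ** 2, axis=-1)
        counts += t1 - t0

    denom = np.sqrt(auto[ia] * auto[ib])  # (n_links, n_ep)
    flagged = [links[i] for i in np.flatnonzero(np.any(denom == 0, axis=1))]
    if flagged:
        warnings.warn(
            f"{len(flagged)} links involve a zero-power channel; coherence NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_epoch = np.abs(num) / denom
        overall = np.abs(num.sum(axis=1)) / np.sqrt(
            auto[ia].sum(axis=1) * auto[ib].sum(axis=1)
        )
    return CoherenceResult(
        links=list(links),
        per_epoch=per_epoch,
        overall=overall,
        band=band,
        kind=epochs.kind,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# rest subtraction, KS masking, network aggregation


@dataclass
class MaskedDifference:
    """Task-minus-rest coherence differences after KS masking.

    ``difference[l]`` is mean(task per-epoch) - mean(rest per-epoch) when
    the two distributions differ at ``alpha`` by the two-sample KS test,
    else 0.  ``insufficient[l]`` marks links zeroed for lack of epochs
    rather than by the test.
    """

    links: list[tuple[str, str]]
    difference: np.ndarray
    ks_p: np.ndarray
    task_mean: np.ndarray
    rest_mean: np.ndarray
    alpha: float
    insufficient: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chan_a": [a for a, _ in self.links],
                "chan_b": [b for _, b in self.links],
                "task_coh": self.task_mean,
                "rest_coh": self.rest_mean,
                "ks_p": self.ks_p,
                "masked_diff": self.difference,
            }
        )

    def link_index_of(self, a: str, b: str) -> int:
        for i, (x, y) in enumerate(self.links):
            if {x, y} == {a, b}:
                return i
        raise KeyError(f"link {a}-{b} not present; network incomplete")


def ks_mask(
    task: CoherenceResult,
    rest: CoherenceResult,
    alpha: float = DEFAULT_ALPHA,
    min_epochs: int = 5,
) -> MaskedDifference:
    """Per-link KS-masked task-minus-rest coherence difference.

    The two-sample Kolmogorov-Smirnov statistic is computed over the
    per-epoch coherence samples of each link; differences with p >= alpha
    are set to zero.  p-values are reported unadjusted.  Links with fewer
    than ``min_epochs`` epochs on either side are zeroed and flagged as
    insufficient (distinguishable from a genuine non-significant zero).
    """
    if task.links != rest.links:
        raise ValueError("task and rest results must share the same link list")
    n_links = len(task.links)
    diff = np.zeros(n_links)
    pvals = np.ones(n_links)
    insufficient = np.zeros(n_links, dtype=bool)
    task_mean = np.full(n_links, np.nan)
    rest_mean = np.full(n_links, np.nan)
    for l in range(n_links):
        ts = task.per_epoch[l][np.isfinite(task.per_epoch[l])]
        rs = rest.per_epoch[l][np.isfinite(rest.per_epoch[l])]
        if len(ts) < min_epochs or len(rs) < min_epochs:
            insufficient[l] = True
            warnings.warn(
                f"link {task.links[l]}: fewer than {min_epochs} epochs; "
                "difference set to 0",
                stacklevel=2,
            )
            continue
        task_mean[l] = ts.mean()
        rest_mean[l] = rs.mean()
        if alpha >= 1.0:  # unmasked pass-through limit
            pvals[l] = 0.0
            diff[l] = task_mean[l] - rest_mean[l]
            continue
        stat = stats.ks_2samp(ts, rs)
        pvals[l] = stat.pvalue
        if stat.pvalue < alpha:
            diff[l] = task_mean[l] - rest_mean[l]
    return MaskedDifference(
        links=list(task.links),
        difference=diff,
        ks_p=pvals,
        task_mean=task_mean,
        rest_mean=rest_mean,
        alpha=alpha,
        insufficient=insufficient,
    )


def network_links(
    networks: dict[str, tuple[tuple[str, str], ...]] = DEFAULT_NETWORKS,
) -> list[tuple[str, str]]:
    """Union of the links named by the network definition (in order)."""
    out: list[tuple[str, str]] = []
    for net in networks.values():
        for link in net:
            if link not in out:
                out.append(link)
    return out


def aggregate_networks(
    masked: MaskedDifference,
    networks: dict[str, tuple[tuple[str, str], ...]] = DEFAULT_NETWORKS,
) -> dict[str, float]:
    """Mean masked difference within each link group.

    Raises ``KeyError`` if a network names a link absent from the result
    (the network would be incomplete).
    """
    out = {}
    for name, net_links in networks.items():
        vals = [masked.difference[masked.link_index_of(a, b)] for a, b in net_links]
        out[name] = float(np.mean(vals))
    return out


def group_average_mask(per_participant: list[MaskedDifference]) -> MaskedDifference:
    """Element-wise mean of masked differences across participants.

    All participants must share the same link list.  The result's ks_p is
    NaN (no single test corresponds to the average).
    """
    if not per_participant:
        raise ValueError("empty group")
    links = per_participant[0].links
    for m in per_participant[1:]:
        if m.links != links:
            raise ValueError("participants have differing link lists")
    diff = np.mean([m.difference for m in per_participant], axis=0)
    return MaskedDifference(
        links=list(links),
        difference=diff,
        ks_p=np.full(len(links), np.nan),
        task_mean=np.nanmean([m.task_mean for m in per_participant], axis=0),
        rest_mean=np.nanmean([m.rest_mean for m in per_participant], axis=0),
        alpha=per_participant[0].alpha,
    )


# ---------------------------------------------------------------------------
# EDF input

def load_edf(path: str | Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Load continuous EEG from an EDF file via mne.

    Returns (data in µV as channels x samples, sampling rate Hz, labels).
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), tuple(raw.ch_names)
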