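"""Metronome sequence generation.

Isochronous and cosine-modulated click sequences for paced finger tapping.
The modulated sequences perturb every other click onset in an alternating
early/late pattern with a period of four stimuli, so the rhythm cannot be
predicted from the preceding interval while the mean rate is preserved.

Onset rule
----------
With baseline inter-stimulus interval ``ISI`` and modulation depth ``m``
(a fraction of the ISI), the k-th click onset is

    onset_k = k * ISI - delta * sin(pi * k / 2),   delta = m * ISI,

rounded half-to-even to integer milliseconds.  Even-index onsets are
unperturbed; odd-index onsets alternate early (k = 1, 5, ...) and late
(k = 3, 7, ...).  At 3% depth of a 1250 ms ISI this yields onsets
0, 1212, 2500, 3788, 5000 ms (intervals 1212-1288-1288-1212 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Condition labels used throughout: isochronous and 3/7/20% modulation.
CONDITION_DEPTHS = {"iso": 0.0, "d3": 0.03, "d7": 0.07, "d20": 0.20}

DEFAULT_ISI_MS = 1250.0
DEFAULT_N_STIMULI = 60


@dataclass(frozen=True)
class StimulusSequence:
    """An ordered metronome click sequence with its design parameters.

    ``onsets`` are integer milliseconds from sequence start (first onset 0);
    ``deviations`` record each onset's signed departure from the isochronous
    grid.  ``boundary_beeps`` flags the 2000 Hz start/end markers of the
    original paradigm (metadata only; no audio is rendered).
    """

    condition_label: str
    baseline_isi: float
    modulation_depth: float
    onsets: np.ndarray
    deviations: np.ndarray
    boundary_beeps: bool = True

    @property
    def n_stimuli(self) -> int:
        return len(self.onsets)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=np.int64)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(
            self, "deviations", np.asarray(self.deviations, dtype=np.int64)
        )
        if onsets[0] != 0:
            raise ValueError("first onset must be 0")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        """Inter-onset intervals in ms."""
        return np.diff(self.onsets)


def condition_from_depth(modulation_depth: float) -> str:
    """Map a modulation depth to its canonical condition label."""
    for label, depth in CONDITION_DEPTHS.items():
        if abs(depth - modulation_depth) < 1e-12:
            return label
    return f"d{modulation_depth * 100:g}"


def generate_sequence(
    n_stimuli: int = DEFAULT_N_STIMULI,
    baseline_isi: float = DEFAULT_ISI_MS,
    modulation_depth: float = 0.0,
    condition_label: str | None = None,
) -> StimulusSequence:
    """Generate an isochronous or cosine-modulated click sequence.

    Parameters
    ----------
    n_stimuli
        Number of clicks (>= 2).
    baseline_isi
        Baseline inter-stimulus interval in ms (> 0); 1250 ms at the
        paradigm's 0.8 Hz rate.
    modulation_depth
        Fraction of the ISI by which perturbed onsets deviate, in
        [0, 0.5).  Depths >= 0.5 would let adjacent onsets collide.

    Returns
    -------
    StimulusSequence
        Integer-ms onsets plus the per-onset deviation record.
    """
    if n_stimuli < 2:
        raise ValueError(f"n_stimuli must be >= 2, got {n_stimuli}")
    if baseline_isi <= 0:
        raise ValueError(f"baseline_isi must be positive, got {baseline_isi}")
    if not 0 <= modulation_depth < 0.5:
        raise ValueError(
            f"modulation_depth must be in [0, 0.5), got {modulation_depth}"
        )
    k = np.arange(n_stimuli)
    delta = modulation_depth * baseline_isi
    exact = k * baseline_isi - delta * np.sin(np.pi * k / 2)
    # np.round is round-half-to-even: 1212.5 -> 1212, 3787.5 -> 3788.
    onsets = np.round(exact).astype(np.int64)
    grid = np.round(k * baseline_isi).astype(np.int64)
    if condition_label is None:
        condition_label = condition_from_depth(modulation_depth)
    return StimulusSequence(
        condition_label=condition_label,
        baseline_isi=float(baseline_isi),
        modulation_depth=float(modulation_depth),
        onsets=onsets,
        deviations=onsets - grid,
    )


def sequence_duration(seq: StimulusSequence) -> float:
    """Nominal sequence duration in seconds.

    By design convention the sequence spans one full baseline interval per
    stimulus: 60 stimuli at 1250 ms last 75 s.
    """
    return seq.n_stimuli * seq.baseline_isi / 1000.0


def isi_from_frequency(freq_hz: float) -> float:
    """Inter-stimulus interval in ms for a click rate in Hz (0.8 -> 1250)."""
    if freq_hz <= 0:
        raise ValueError(f"frequency must be positive, got {freq_hz}")
    return 1000.0 / freq_hz


def write_onsets(seq: StimulusSequence, path: str | Path) -> None:
    """Write a sequence to the delimited onsets format.

    Columns ``index, onset_ms, deviation_ms`` (tab-separated, one header
    line, 0-based index, integer ms).
    """
    df = pd.DataFrame(
        {
            "index": np.arange(seq.n_stimuli),
            "onset_ms": seq.onsets,
            "deviation_ms": seq.deviations,
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# condition={seq.condition_label} baseline_isi={seq.baseline_isi:g}"
            f" modulation_depth={seq.modulation_depth:g}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_onsets(path: str | Path) -> StimulusSequence:
    """Read a sequence written by :func:`write_onsets` (bit-exact round trip)."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(item.split("=") for item in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    onsets = df["onset_ms"].to_numpy(dtype=np.int64)
    return StimulusSequence(
        condition_label=meta["condition"],
        baseline_isi=float(meta["baseline_isi"]),
        modulation_depth=float(meta["modulation_depth"]),
        onsets=onsets,
        deviations=df["deviation_ms"].to_numpy(dtype=np.int64),
    )
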