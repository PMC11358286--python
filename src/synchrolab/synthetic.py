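"""Synthetic cohorts for end-to-end validation of the analysis pipeline.

Generates the three study-like groups -- children with developmental
coordination disorder (DCD), typically developing children (TD), and
typically developing musicians (TDM) -- as

* finger-tap trains from a linear phase-correction tapper with
  group-dependent negative mean asynchrony and variability,
* logistic psychometric observers for the staircase tasks, and
* 32-channel EEG whose beta-band coupling differs controllably between
  the interhemispheric, midline and intrahemispheric link groups.

All randomness flows from one cohort seed through per-participant
``numpy.random.SeedSequence`` children, so identical seeds give
byte-identical datasets.

Tapper model
------------
The tapper is the standard linear phase-correction process of paced
tapping: with asynchrony A_n = tap_n - click_n, correction gain
``alpha`` in (0, 1], preferred asynchrony ``nma_offset`` (negative =
anticipatory), timekeeper noise T_n and motor noise M_n,

    tap_{n+1} = tap_n + ISI - alpha (A_n - nma) + T_n + M_{n+1} - M_n,

equivalently A_{n+1} = (1-alpha) A_n + alpha nma + T_n + dM - (d_{n+1} - d_n)
where d_n is the stimulus-onset deviation from isochrony.  Its stationary
asynchrony SD has the closed form

    var(A) = sd_T^2 / (1 - beta^2) + 2 sd_M^2 / (1 + beta),  beta = 1 - alpha,

used to calibrate the timekeeper noise to a target variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf
from .psychophysics import ObserverModel
from .stimulus import (
    CONDITION_DEPTHS,
    DEFAULT_ISI_MS,
    DEFAULT_N_STIMULI,
    StimulusSequence,
    generate_sequence,
    write_onsets,
)
from .tapping import TapTrain
from .eeg import DEFAULT_NETWORKS, DEFAULT_SFREQ

GROUPS = ("DCD", "TD", "TDM")
DEFAULT_GROUP_SIZES = {"DCD": 9, "TD": 11, "TDM": 12}
CONDITIONS = ("iso", "d3", "d7", "d20")


# ---------------------------------------------------------------------------
# tapper


@dataclass(frozen=True)
class TapperModel:
    """Linear phase-correction tapper.

    ``nma_offset`` is the preferred (mean) asynchrony in ms, negative for
    anticipatory tapping; ``reactive_mode`` marks presets that emulate
    reactive tapping at large perturbations (asynchrony near zero, high
    variability) -- it changes no equations, only labels the regime.
    ``double_tap_rate`` is the per-tap probability of a spurious extra tap
    within 100 ms, exercising the double-tap exclusion rule.
    """

    alpha: float = 0.5
    nma_offset: float = -50.0
    timekeeper_sd: float = 20.0
    motor_sd: float = 10.0
    reactive_mode: bool = False
    double_tap_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.timekeeper_sd < 0 or self.motor_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.double_tap_rate < 1:
            raise ValueError("double_tap_rate must be in [0, 1)")


def stationary_asynchrony_sd(model: TapperModel) -> float:
    """Stationary SD of the asynchrony under an isochronous metronome."""
    beta = 1.0 - model.alpha
    var = model.timekeeper_sd**2 / (1 - beta**2) + 2 * model.motor_sd**2 / (1 + beta)
    return float(np.sqrt(var))


def tapper_from_targets(
    nma: float,
    target_sd: float,
    alpha: float = 0.5,
    motor_sd: float = 10.0,
    reactive_mode: bool = False,
    double_tap_rate: float = 0.0,
) -> TapperModel:
    """Build a tapper whose stationary mean/SD of asynchrony hit targets.

    Solves the stationary-variance formula for the timekeeper SD; raises
    if the motor noise alone already exceeds the target variability.
    """
    beta = 1.0 - alpha
    resid = target_sd**2 - 2 * motor_sd**2 / (1 + beta)
    if resid < 0:
        raise ValueError(
            f"target SD {target_sd} unreachable with motor_sd {motor_sd}"
        )
    return TapperModel(
        alpha=alpha,
        nma_offset=nma,
        timekeeper_sd=float(np.sqrt(resid * (1 - beta**2))),
        motor_sd=motor_sd,
        reactive_mode=reactive_mode,
        double_tap_rate=double_tap_rate,
    )


def simulate_taps(
    model: TapperModel,
    seq: StimulusSequence,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    run_index: int = 1,
) -> TapTrain:
    """Simulate one tap train against a stimulus sequence.

    One tap per click (started at the stationary asynchrony distribution),
    plus optional spurious double taps at ``model.double_tap_rate``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clicks = seq.onsets.astype(float)
    n = len(clicks)
    isi = seq.baseline_isi
    a0_sd = stationary_asynchrony_sd(model)
    motor = rng.normal(0.0, model.motor_sd, size=n)
    timekeeper = rng.normal(0.0, model.timekeeper_sd, size=n)
    taps = np.empty(n)
    asyn = model.nma_offset + (rng.normal(0.0, a0_sd) if a0_sd > 0 else 0.0)
    taps[0] = clicks[0] + asyn + motor[0]
    for k in range(n - 1):
        a_obs = taps[k] - clicks[k]
        taps[k + 1] = (
            taps[k]
            + isi
            - model.alpha * (a_obs - model.nma_offset)
            + timekeeper[k]
            + motor[k + 1]
            - motor[k]
        )
    out = list(taps)
    if model.double_tap_rate > 0:
        for t in taps:
            if rng.random() < model.double_tap_rate:
                out.append(t + rng.uniform(20.0, 80.0))
    return TapTrain(
        participant_id=participant_id,
        condition_label=seq.condition_label,
        run_index=run_index,
        taps=np.sort(np.asarray(out)),
    )


# ---------------------------------------------------------------------------
# group presets (scaled to the magnitudes typical of 7-11 year-old tappers)

#: (mean asynchrony ms, asynchrony SD ms) per group x condition.
TAPPER_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    "DCD": {"iso": (-116.91, 183.17), "d3": (-111.27, 181.05),
            "d7": (-139.11, 190.83), "d20": (-18.13, 317.24)},
    "TD": {"iso": (-48.72, 125.76), "d3": (-46.07, 149.19),
           "d7": (-53.43, 163.13), "d20": (-17.95, 275.51)},
    "TDM": {"iso": (-50.75, 85.98), "d3": (-58.49, 104.86),
            "d7": (-62.09, 130.95), "d20": (16.50, 236.92)},
}

#: Staircase observer thresholds per group (rhythm / duration tasks).
OBSERVER_THRESHOLDS: dict[str, dict[str, float]] = {
    "DCD": {"rhythm": 22.18, "duration": 34.56},
    "TD": {"rhythm": 19.19, "duration": 35.15},
    "TDM": {"rhythm": 14.27, "duration": 30.79},
}

#: Per-run probability of reporting a rhythmic change, per group x condition.
#: Calibrated so coded both-run accuracies sit at child-study magnitudes:
#: near-ceiling detection at 20% modulation, near-floor at 3%, intermediate
#: at 7%, and group-dependent false alarms on the isochronous sequence.
DETECTION_PROBABILITY: dict[str, dict[str, float]] = {
    "DCD": {"iso": 0.25, "d3": 0.33, "d7": 0.67, "d20": 1.0},
    "TD": {"iso": 0.10, "d3": 0.10, "d7": 0.60, "d20": 1.0},
    "TDM": {"iso": 0.00, "d3": 0.41, "d7": 0.76, "d20": 1.0},
}

#: Task-EEG beta coupling per group x condition x network.  Rest coupling is
#: EEG_REST_COUPLING for every link; a task coupling equal to it yields a
#: null (masked-out) difference.  TD groups gain interhemispheric coupling
#: under the large perturbation; musicians also at baseline; the DCD preset
#: is flat across conditions.
EEG_REST_COUPLING = 0.3
EEG_TASK_COUPLING: dict[str, dict[str, dict[str, float]]] = {
    "DCD": {
        "iso": {"intrahemispheric": 0.3, "midline": 0.3, "interhemispheric": 0.3},
        "d20": {"intrahemispheric": 0.3, "midline": 0.3, "interhemispheric": 0.3},
    },
    "TD": {
        "iso": {"intrahemispheric": 0.3, "midline": 0.3, "interhemispheric": 0.3},
        "d20": {"intrahemispheric": 0.3, "midline": 0.3, "interhemispheric": 1.0},
    },
    "TDM": {
        "iso": {"intrahemispheric": 0.3, "midline": 0.3, "interhemispheric": 0.8},
        "d20": {"intrahemispheric": 0.4, "midline": 0.3, "interhemispheric": 1.2},
    },
}

#: 32-channel montage (modified 10-20) including the fronto-central
#: network channels and the excluded posterior row.
MONTAGE_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz",
    "PO7", "PO3", "PO4", "PO8", "Oz",
)


def group_observer(group: str, task: str = "rhythm") -> ObserverModel:
    """Staircase observer preset for a group (rhythm or duration task)."""
    return ObserverModel(
        threshold=OBSERVER_THRESHOLDS[group][task],
        slope=0.5,
        lapse_rate=0.02,
        guess_rate=0.0,
    )


def group_tapper(group: str, condition: str, double_tap_rate: float = 0.0) -> TapperModel:
    """Tapper preset for a group x condition cell."""
    nma, sd = TAPPER_TARGETS[group][condition]
    return tapper_from_targets(
        nma=nma,
        target_sd=sd,
        reactive_mode=(condition == "d20"),
        double_tap_rate=double_tap_rate,
    )


# ---------------------------------------------------------------------------
# EEG generator


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sfreq: float, sd: float) -> np.ndarray:
    """1/f-amplitude background noise, per-channel independent, SD ``sd``."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (
        rng.standard_normal((n_channels, len(freqs)))
        + 1j * rng.standard_normal((n_channels, len(freqs)))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return sd * x


def _beta_source(rng: np.random.Generator, n_samples: int, sfreq: float,
                 band: tuple[float, float] = (12.0, 30.0)) -> np.ndarray:
    """Unit-SD band-limited (beta) noise source."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros(len(freqs), dtype=complex)
    spec[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    x = np.fft.irfft(spec, n=n_samples)
    return x / x.std()


def simulate_eeg(
    coupling: dict[str, float],
    duration_s: float,
    tap_times_ms: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    sfreq: float = DEFAULT_SFREQ,
    channel_labels: tuple[str, ...] = MONTAGE_32,
    networks: dict[str, tuple[tuple[str, str], ...]] = DEFAULT_NETWORKS,
    noise_sd: float = 10.0,
    source_sd: float = 10.0,
    tap_locked_gain: float = 0.5,
) -> np.ndarray:
    """Synthesize continuous multi-channel EEG with planted link coupling.

    Each channel carries independent pink background noise; for every link
    of every network a shared beta-band source is mixed into the link's two
    channels with weight ``coupling[network] * source_sd`` (µV).  When tap
    times are given, the source amplitude is additionally modulated by
    Gaussian bumps (SD 100 ms) jittered around each tap, emulating
    movement-locked synchronization.

    Returns (channels, samples) in µV.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(duration_s * sfreq))
    data = _pink_noise(rng, len(channel_labels), n_samples, sfreq, noise_sd)
    idx = {ch: i for i, ch in enumerate(channel_labels)}
    t = np.arange(n_samples) / sfreq  # seconds

    envelope = np.ones(n_samples)
    if tap_times_ms is not None and tap_locked_gain > 0 and len(tap_times_ms):
        jitter = rng.normal(0.0, 0.02, size=len(tap_times_ms))
        centers = np.asarray(tap_times_ms, float) / 1000.0 + jitter
        for c in centers:
            envelope += tap_locked_gain * np.exp(-0.5 * ((t - c) / 0.1) ** 2)

    for net_name, links in networks.items():
        w = coupling.get(net_name, 0.0) * source_sd
        for a, b in links:
            if a not in idx or b not in idx:
                raise ValueError(f"montage lacks channel for link {a}-{b}")
            if w == 0:
                continue
            source = _beta_source(rng, n_samples, sfreq) * envelope
            data[idx[a]] += w * source
            data[idx[b]] += w * source
    return data


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults are the study-like conditions: group sizes 9/11/12, four
    conditions repeated twice at 60 stimuli x 1250 ms, EEG for the
    isochronous and 20%-modulation contrast, 30-s rest per participant.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_stimuli: int = DEFAULT_N_STIMULI
    baseline_isi: float = DEFAULT_ISI_MS
    n_runs: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    eeg_conditions: tuple[str, ...] = ("iso", "d20")
    include_eeg: bool = True
    double_tap_rate: float = 0.02
    eeg_lead_in_s: float = 2.0
    rest_duration_s: float = 30.0
    seed: int = 0

    def participants(self) -> list[tuple[str, str]]:
        """(participant_id, group) pairs, deterministic order."""
        out = []
        for g in GROUPS:
            for i in range(self.group_sizes.get(g, 0)):
                out.append((f"{g.lower()}{i + 1:02d}", g))
        return out


def participant_rngs(spec: CohortSpec) -> dict[str, np.random.Generator]:
    """Per-participant generators spawned from the cohort seed.

    Uses ``SeedSequence(seed).spawn`` in participant order, so any one
    participant's data is independent of the others and reproducible.
    """
    parts = spec.participants()
    children = np.random.SeedSequence(spec.seed).spawn(len(parts))
    return {pid: np.random.default_rng(ss) for (pid, _), ss in zip(parts, children)}


def simulate_participant_taps(
    spec: CohortSpec, group: str, pid: str, rng: np.random.Generator
) -> tuple[list[TapTrain], list[dict]]:
    """All tap trains and verbal-response rows for one participant."""
    trains = []
    responses = []
    for cond in spec.conditions:
        seq = generate_sequence(
            spec.n_stimuli, spec.baseline_isi, CONDITION_DEPTHS[cond]
        )
        model = group_tapper(group, cond, double_tap_rate=spec.double_tap_rate)
        truth = CONDITION_DEPTHS[cond] > 0
        p_yes = DETECTION_PROBABILITY[group][cond]
        for run in range(1, spec.n_runs + 1):
            trains.append(
                simulate_taps(model, seq, seed=rng, participant_id=pid, run_index=run)
            )
            reported = bool(rng.random() < p_yes)
            responses.append(
                {
                    "participant": pid,
                    "group": group,
                    "condition": cond,
                    "run": run,
                    "reported_change": reported,
                    "truth": truth,
                }
            )
    return trains, responses


def simulate_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write a full synthetic dataset consumable by the pipeline.

    Layout::

        out_dir/
          manifest.json           seeds, sizes, design parameters
          stimuli/<cond>.tsv      onset files
          taps.tsv                tap log (all participants)
          responses.tsv           verbal-response log
          eeg/<pid>_<cond>_run<k>.edf + _events.tsv   task EEG (if enabled)
          eeg/<pid>_rest.edf      30-s rest recording

    Task EEG covers ``spec.eeg_conditions`` only (the contrast analysis);
    tap times in the event files are relative to recording start (the
    sequence starts after ``eeg_lead_in_s``).
    """
    out = Path(out_dir)
    (out / "stimuli").mkdir(parents=True, exist_ok=True)
    if spec.include_eeg:
        (out / "eeg").mkdir(exist_ok=True)

    for cond in spec.conditions:
        seq = generate_sequence(spec.n_stimuli, spec.baseline_isi, CONDITION_DEPTHS[cond])
        write_onsets(seq, out / "stimuli" / f"{cond}.tsv")

    rngs = participant_rngs(spec)
    all_trains: list[TapTrain] = []
    all_responses: list[dict] = []
    groups_map: dict[str, str] = {}
    for pid, group in spec.participants():
        rng = rngs[pid]
        groups_map[pid] = group
        trains, responses = simulate_participant_taps(spec, group, pid, rng)
        all_trains.extend(trains)
        all_responses.extend(responses)
        if spec.include_eeg:
            _write_participant_eeg(spec, group, pid, trains, rng, out / "eeg")

    from .tapping import write_tap_log

    write_tap_log(all_trains, groups_map, out / "taps.tsv")
    pd.DataFrame(all_responses).to_csv(out / "responses.tsv", sep="\t", index=False)
    manifest = {
        "seed": spec.seed,
        "group_sizes": spec.group_sizes,
        "n_stimuli": spec.n_stimuli,
        "baseline_isi": spec.baseline_isi,
        "n_runs": spec.n_runs,
        "conditions": list(spec.conditions),
        "eeg_conditions": list(spec.eeg_conditions) if spec.include_eeg else [],
        "eeg_lead_in_s": spec.eeg_lead_in_s,
        "rest_duration_s": spec.rest_duration_s,
        "participants": {pid: g for pid, g in spec.participants()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _write_participant_eeg(
    spec: CohortSpec,
    group: str,
    pid: str,
    trains: list[TapTrain],
    rng: np.random.Generator,
    eeg_dir: Path,
) -> None:
    duration = spec.eeg_lead_in_s + spec.n_stimuli * spec.baseline_isi / 1000.0 + 1.0
    duration = float(np.ceil(duration))
    rest_coupling = {net: EEG_REST_COUPLING for net in DEFAULT_NETWORKS}
    for cond in spec.eeg_conditions:
        coupling = EEG_TASK_COUPLING[group][cond]
        for train in (t for t in trains if t.condition_label == cond):
            tap_ms = train.taps + spec.eeg_lead_in_s * 1000.0
            data = simulate_eeg(
                coupling, duration, tap_times_ms=tap_ms, seed=rng
            )
            stem = f"{pid}_{cond}_run{train.run_index}"
            _edf.write_edf(eeg_dir / f"{stem}.edf", data, DEFAULT_SFREQ, MONTAGE_32)
            pd.DataFrame({"tap_ms": tap_ms}).to_csv(
                eeg_dir / f"{stem}_events.tsv", sep="\t", index=False
            )
    rest = simulate_eeg(rest_coupling, spec.rest_duration_s, seed=rng)
    _edf.write_edf(eeg_dir / f"{pid}_rest.edf", rest, DEFAULT_SFREQ, MONTAGE_32)
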