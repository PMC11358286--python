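"""Tap-train cleaning and synchronization metrics.

Raw finger-tap trains are cleaned in a fixed order -- warm-up discard,
double-tap removal, inter-tap-interval (ITI) outlier removal -- then each
retained tap is matched to its nearest metronome click and summarized as
mean/SD of the ITI (tapping rate and consistency) and of the signed
synchronization error SE = tap - click (negative SE means the tap preceded
the beat, the anticipatory mode typical of paced tapping).

Double taps are removed before the ITI rule because a spurious extra tap
corrupts the intervals on both sides of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import StimulusSequence

VALID = "none"
WARMUP = "warmup"
DOUBLE_TAP = "double_tap"
ITI_OUTLIER = "iti_outlier"

DEFAULT_N_WARMUP = 10
DEFAULT_MIN_GAP_MS = 100.0
DEFAULT_ITI_TOLERANCE = 0.5


@dataclass(frozen=True)
class TapTrain:
    """Tap onsets (ms) for one participant x condition x run, with per-tap
    exclusion annotations (``none | warmup | double_tap | iti_outlier``)."""

    participant_id: str
    condition_label: str
    run_index: int
    taps: np.ndarray
    exclusions: np.ndarray | None = None

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if self.exclusions is None:
            object.__setattr__(
                self, "exclusions", np.full(len(taps), VALID, dtype=object)
            )
        else:
            excl = np.asarray(self.exclusions, dtype=object)
            if len(excl) != len(taps):
                raise ValueError("exclusions must annotate every tap")
            object.__setattr__(self, "exclusions", excl)
        valid = self.valid_taps
        if np.any(np.diff(valid) <= 0):
            raise ValueError("valid taps must be strictly increasing")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.exclusions == VALID

    @property
    def valid_taps(self) -> np.ndarray:
        return self.taps[self.valid_mask]

    def exclusion_counts(self) -> dict[str, int]:
        return {
            reason: int(np.sum(self.exclusions == reason))
            for reason in (VALID, WARMUP, DOUBLE_TAP, ITI_OUTLIER)
        }


@dataclass(frozen=True)
class SyncSummary:
    """Per-condition synchronization measures (the Table-2-style row unit).

    ``mean_se`` is the signed tap-to-click offset in ms; negative values
    mean taps preceded the beat.  ``valid`` is False when fewer than two
    matched pairs were available.
    """

    mean_iti: float
    sd_iti: float
    mean_se: float
    sd_se: float
    n_valid_taps: int
    valid: bool = True


def discard_warmup(train: TapTrain, n_discard: int = DEFAULT_N_WARMUP) -> TapTrain:
    """Annotate the first ``n_discard`` taps as warm-up.

    The opening taps of each sequence reflect initial tempo adjustment and
    are excluded from analysis (default 10).
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    excl = train.exclusions.copy()
    candidates = np.flatnonzero(excl == VALID)[:n_discard]
    excl[candidates] = WARMUP
    if not np.any(excl == VALID) and len(train.taps) > 0:
        warnings.warn(
            f"{train.participant_id}/{train.condition_label} run {train.run_index}: "
            "no taps remain after warm-up discard",
            stacklevel=2,
        )
    return replace(train, exclusions=excl)


def remove_double_taps(train: TapTrain, min_gap: float = DEFAULT_MIN_GAP_MS) -> TapTrain:
    """Annotate the second of two taps closer than ``min_gap`` ms as a double tap.

    Scans left to right over currently valid taps; the earlier tap is kept
    and comparison continues from it.
    """
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")
    excl = train.exclusions.copy()
    last_kept = None
    for i in np.flatnonzero(excl == VALID):
        if last_kept is not None and train.taps[i] - train.taps[last_kept] < min_gap:
            excl[i] = DOUBLE_TAP
        else:
            last_kept = i
    return replace(train, exclusions=excl)


def remove_iti_outliers(
    train: TapTrain,
    seq: StimulusSequence,
    tolerance: float = DEFAULT_ITI_TOLERANCE,
) -> TapTrain:
    """Annotate taps whose preceding inter-tap interval is more than
    ``tolerance`` (default 50%) longer or shorter than the target interval.

    The target is the condition's baseline ISI.  After a too-short
    exclusion the comparison continues from the last retained tap (the
    interval is recomputed over retained taps, so bursts cannot sneak in);
    after a too-long exclusion the excluded tap becomes the new reference
    -- a long gap signals missed taps, and re-anchoring prevents one gap
    from cascading into the exclusion of every later tap.
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    target = seq.baseline_isi
    lo, hi = (1 - tolerance) * target, (1 + tolerance) * target
    excl = train.exclusions.copy()
    anchor = None
    for i in np.flatnonzero(excl == VALID):
        if anchor is not None:
            iti = train.taps[i] - train.taps[anchor]
            if iti < lo:
                excl[i] = ITI_OUTLIER
                continue
            if iti > hi:
                excl[i] = ITI_OUTLIER
                anchor = i
                continue
        anchor = i
    return replace(train, exclusions=excl)


def clean(
    train: TapTrain,
    seq: StimulusSequence,
    n_warmup: int = DEFAULT_N_WARMUP,
    min_gap: float = DEFAULT_MIN_GAP_MS,
    iti_tolerance: float = DEFAULT_ITI_TOLERANCE,
) -> TapTrain:
    """Apply the full cleaning pipeline in its fixed order."""
    train = discard_warmup(train, n_warmup)
    train = remove_double_taps(train, min_gap)
    return remove_iti_outliers(train, seq, iti_tolerance)


@dataclass(frozen=True)
class MatchResult:
    """Tap-to-click assignment: matched (tap, click) pairs plus leftovers."""

    pairs: np.ndarray  # shape (n, 2): tap_ms, click_ms
    unmatched_taps: np.ndarray
    unmatched_clicks: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        """Signed synchronization errors tap - click in ms."""
        if len(self.pairs) == 0:
            return np.empty(0)
        return self.pairs[:, 0] - self.pairs[:, 1]


def match_taps(train: TapTrain, seq: StimulusSequence) -> MatchResult:
    """Pair each valid tap with its nearest click.

    The signed offset tap - click must lie in (-ISI/2, +ISI/2] (half-open,
    so a tap exactly midway between two clicks pairs with the earlier one
    at offset +ISI/2).  At most one tap per click; the nearest tap wins,
    the earlier tap on an exact |offset| tie.
    """
    taps = train.valid_taps
    onsets = seq.onsets.astype(float)
    half = seq.baseline_isi / 2.0
    # best candidate click per tap under the half-open window
    best: dict[int, tuple[float, float]] = {}  # click idx -> (|offset|, tap)
    unmatched_taps: list[float] = []
    for tap in taps:
        j = int(np.searchsorted(onsets, tap))
        cand = None
        for c in (j - 1, j):
            if 0 <= c < len(onsets):
                off = tap - onsets[c]
                if -half < off <= half:
                    if cand is None or abs(off) < abs(tap - onsets[cand]):
                        cand = c
        if cand is None:
            unmatched_taps.append(tap)
            continue
        key = (abs(tap - onsets[cand]), tap)
        if cand not in best or key < best[cand]:
            if cand in best:
                unmatched_taps.append(best[cand][1])
            best[cand] = key
        else:
            unmatched_taps.append(tap)
    pairs = np.array(
        sorted((best[c][1], onsets[c]) for c in best), dtype=float
    ).reshape(-1, 2)
    matched_clicks = {onsets[c] for c in best}
    unmatched_clicks = np.array(
        [o for o in onsets if o not in matched_clicks], dtype=float
    )
    return MatchResult(
        pairs=pairs,
        unmatched_taps=np.array(sorted(unmatched_taps), dtype=float),
        unmatched_clicks=unmatched_clicks,
    )


def summarize(train: TapTrain, seq: StimulusSequence) -> SyncSummary:
    """Compute the synchronization summary for one cleaned run.

    SE statistics are over matched tap-click offsets; ITI statistics over
    intervals between retained taps.  SDs are sample SDs (ddof=1).
    """
    match = match_taps(train, seq)
    offsets = match.offsets
    valid_taps = train.valid_taps
    itis = np.diff(valid_taps)
    if len(offsets) < 2:
        return SyncSummary(
            mean_iti=float("nan"),
            sd_iti=float("nan"),
            mean_se=float(np.mean(offsets)) if len(offsets) else float("nan"),
            sd_se=float("nan"),
            n_valid_taps=len(valid_taps),
            valid=False,
        )
    return SyncSummary(
        mean_iti=float(np.mean(itis)),
        sd_iti=float(np.std(itis, ddof=1)),
        mean_se=float(np.mean(offsets)),
        sd_se=float(np.std(offsets, ddof=1)),
        n_valid_taps=len(valid_taps),
    )


def average_runs(summaries: list[SyncSummary]) -> SyncSummary:
    """Average the per-run summaries of one condition.

    The two runs of each condition are averaged statistic-by-statistic to
    stabilize the values; an early-terminated session contributes its
    single run unchanged.  Invalid runs are dropped first.
    """
    usable = [s for s in summaries if s.valid]
    if not usable:
        raise ValueError("no valid run summaries to average")
    return SyncSummary(
        mean_iti=float(np.mean([s.mean_iti for s in usable])),
        sd_iti=float(np.mean([s.sd_iti for s in usable])),
        mean_se=float(np.mean([s.mean_se for s in usable])),
        sd_se=float(np.mean([s.sd_se for s in usable])),
        n_valid_taps=int(sum(s.n_valid_taps for s in usable)),
    )


def code_verbal_responses(responses: list[bool]) -> bool | None:
    """Code a condition's verbal reports as correct/incorrect.

    Each run yields one yes/no accuracy flag; both must be accurate for the
    condition to be coded correct.  A single response (early-terminated
    session) is coded from that response alone.  Zero responses -> None
    (missing, excluded from rates).
    """
    if len(responses) == 0:
        return None
    if len(responses) > 2:
        raise ValueError("at most two responses per condition")
    return all(responses)


# ---------------------------------------------------------------------------
# delimited-text I/O

TAP_LOG_COLUMNS = ["participant", "group", "condition", "run", "tap_ms"]
RESPONSE_LOG_COLUMNS = [
    "participant", "group", "condition", "run", "reported_change", "truth",
]


def write_tap_log(trains: list[TapTrain], groups: dict[str, str], path: str | Path) -> None:
    """Write tap trains to the tab-delimited tap-log format."""
    rows = [
        (t.participant_id, groups[t.participant_id], t.condition_label, t.run_index, tap)
        for t in trains
        for tap in t.taps
    ]
    pd.DataFrame(rows, columns=TAP_LOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tap_log(path: str | Path) -> tuple[list[TapTrain], dict[str, str]]:
    """Read a tap log; returns trains plus the participant -> group map."""
    df = pd.read_csv(path, sep="\t", dtype={"participant": str, "group": str})
    missing = set(TAP_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing tap-log columns {sorted(missing)}")
    trains = []
    groups: dict[str, str] = {}
    for (pid, grp, cond, run), sub in df.groupby(
        ["participant", "group", "condition", "run"], sort=True
    ):
        groups[pid] = grp
        trains.append(
            TapTrain(
                participant_id=pid,
                condition_label=cond,
                run_index=int(run),
                taps=np.sort(sub["tap_ms"].to_numpy(dtype=float)),
            )
        )
    return trains, groups
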