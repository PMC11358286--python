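"""Pipeline orchestration and study-shaped output tables.

Reads a dataset directory (tap logs, verbal-response logs, onset files and
optionally task/rest EEG), runs the cleaning, synchronization, verbal-
response and coherence analyses, and writes:

* a synchronization summary table (group means of mean/SD of ITI and SE
  per condition),
* a verbal-response accuracy table (percent correct per group x
  condition, one decimal),
* per-link and per-network masked coherence-difference tables plus a
  matrix-style difference figure,
* a machine-readable run manifest.

Inferential statistics (mixed-design ANOVA, post-hoc contrasts) are
delegated to standard routines (pingouin) behind
:func:`delegated_mixed_anova`; they are reported with effect sizes and
labeled as delegated, not re-implemented.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import eeg as eeg_mod
from . import tapping
from .stimulus import StimulusSequence, read_onsets
from .tapping import SyncSummary

MEASURES = ("mean_iti", "sd_iti", "mean_se", "sd_se")


# ---------------------------------------------------------------------------
# table builders (pure functions of their inputs)


def participant_summaries(
    trains: list[tapping.TapTrain],
    sequences: dict[str, StimulusSequence],
) -> pd.DataFrame:
    """Clean every train, summarize runs, and average runs per condition.

    Returns one row per participant x condition with the four
    synchronization measures.
    """
    rows = []
    by_key: dict[tuple[str, str], list[SyncSummary]] = {}
    for train in trains:
        seq = sequences[train.condition_label]
        cleaned = tapping.clean(train, seq)
        by_key.setdefault((train.participant_id, train.condition_label), []).append(
            tapping.summarize(cleaned, seq)
        )
    for (pid, cond), summaries in sorted(by_key.items()):
        avg = tapping.average_runs(summaries)
        rows.append(
            {
                "participant": pid,
                "condition": cond,
                "mean_iti": avg.mean_iti,
                "sd_iti": avg.sd_iti,
                "mean_se": avg.mean_se,
                "sd_se": avg.sd_se,
                "n_valid_taps": avg.n_valid_taps,
            }
        )
    return pd.DataFrame(rows)


def build_sync_table(
    summaries: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Group-level synchronization table (Table-2-style).

    Rows: measure x condition; columns: group mean (and between-subject SD)
    of the per-participant values.  Negative means are preserved (taps
    preceding the beat).  Missing group x condition cells are NaN.
    """
    if summaries.empty:
        raise ValueError("no participant summaries supplied")
    df = summaries.copy()
    df["group"] = df["participant"].map(groups)
    rows = []
    for measure in MEASURES:
        for cond, sub in df.groupby("condition", sort=False):
            row = {"measure": measure, "condition": cond}
            for grp, gsub in sub.groupby("group"):
                row[f"{grp}_mean"] = float(gsub[measure].mean())
                row[f"{grp}_sd"] = (
                    float(gsub[measure].std(ddof=1)) if len(gsub) > 1 else 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows)


def code_condition_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-run verbal reports to one correct/incorrect flag per
    participant x condition (both runs must be accurate)."""
    rows = []
    for (pid, grp, cond), sub in responses.groupby(
        ["participant", "group", "condition"], sort=True
    ):
        accurate = (sub["reported_change"] == sub["truth"]).tolist()
        coded = tapping.code_verbal_responses(accurate)
        rows.append(
            {"participant": pid, "group": grp, "condition": cond, "correct": coded}
        )
    return pd.DataFrame(rows)


def build_response_table(coded: pd.DataFrame) -> pd.DataFrame:
    """Percent-correct verbal-response table (Table-3-style), one decimal.

    Cells with no coded responses are NaN (marked missing).
    """
    rows = []
    for cond, sub in coded.groupby("condition", sort=False):
        row = {"condition": cond}
        for grp, gsub in sub.groupby("group"):
            vals = gsub["correct"].dropna()
            row[grp] = (
                round(100.0 * vals.mean(), 1) if len(vals) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coherence branch


@dataclass
class CoherenceConfig:
    band: tuple[float, float] = eeg_mod.DEFAULT_BAND
    alpha: float = eeg_mod.DEFAULT_ALPHA
    n_cycles: float = eeg_mod.DEFAULT_N_CYCLES
    links: str = "networks"  # "networks" | "all"


def participant_coherence(
    task_runs: list[tuple[np.ndarray, np.ndarray]],
    rest_data: np.ndarray,
    sfreq: float,
    channel_labels: tuple[str, ...],
    config: CoherenceConfig = CoherenceConfig(),
) -> eeg_mod.MaskedDifference:
    """Task-vs-rest masked coherence differences for one participant x
    condition.

    ``task_runs`` is a list of (continuous data, tap times ms) pairs, one
    per run; their epochs are pooled (two 60-stimulus runs minus warm-up
    give the ~100 epochs per condition) before coherence and masking.
    """
    epoch_sets = [
        eeg_mod.epoch_task(data, sfreq, taps, channel_labels).connectivity_view()
        for data, taps in task_runs
    ]
    task_epochs = eeg_mod.EpochSet(
        data=np.concatenate([e.data for e in epoch_sets], axis=1),
        sfreq=sfreq,
        window=epoch_sets[0].window,
        channel_labels=epoch_sets[0].channel_labels,
        kind="task",
    )
    epoch_len = eeg_mod.TASK_WINDOW[1] - eeg_mod.TASK_WINDOW[0]
    rest_epochs = eeg_mod.epoch_rest(
        rest_data, sfreq, epoch_len, channel_labels
    ).connectivity_view()
    links = (
        eeg_mod.network_links()
        if config.links == "networks"
        else eeg_mod.all_pairs(task_epochs.channel_labels)
    )
    task_coh = eeg_mod.wavelet_coherence(
        task_epochs, config.band, config.n_cycles, links=links
    )
    rest_coh = eeg_mod.wavelet_coherence(
        rest_epochs, config.band, config.n_cycles, links=links
    )
    return eeg_mod.ks_mask(task_coh, rest_coh, config.alpha)


def network_table(
    per_participant: dict[tuple[str, str], eeg_mod.MaskedDifference],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Group-mean network differences: one row per group x condition."""
    rows = []
    keys = sorted({(groups[pid], cond) for (pid, cond) in per_participant})
    for grp, cond in keys:
        members = [
            m
            for (pid, c), m in per_participant.items()
            if groups[pid] == grp and c == cond
        ]
        grp_mask = eeg_mod.group_average_mask(members)
        nets = eeg_mod.aggregate_networks(grp_mask)
        rows.append({"group": grp, "condition": cond, "n": len(members), **nets})
    return pd.DataFrame(rows)


def plot_difference_matrix(
    masked: eeg_mod.MaskedDifference, path: str | Path, title: str = ""
) -> None:
    """Matrix-style plot of masked coherence differences."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chans = sorted({c for link in masked.links for c in link})
    idx = {c: i for i, c in enumerate(chans)}
    mat = np.full((len(chans), len(chans)), np.nan)
    for (a, b), d in zip(masked.links, masked.difference):
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = d
    fig, ax = plt.subplots(figsize=(6, 5))
    vmax = np.nanmax(np.abs(mat)) or 1.0
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(chans)), chans, rotation=90, fontsize=7)
    ax.set_yticks(range(len(chans)), chans, fontsize=7)
    ax.set_title(title or "Task - rest coherence difference (masked)")
    fig.colorbar(im, ax=ax, label="coherence difference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# delegated inferential statistics


def delegated_mixed_anova(
    summaries: pd.DataFrame, groups: dict[str, str], measure: str = "sd_se"
) -> pd.DataFrame:
    """Mixed-design ANOVA (group x condition) on one measure -- DELEGATED.

    Thin wrapper over ``pingouin.mixed_anova``; returns its table (with
    partial eta-squared effect sizes) tagged ``delegated=True``.  Requires
    pingouin; raises ImportError with guidance otherwise.
    """
    try:
        import pingouin as pg
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "delegated statistics require pingouin (install extra 'test')"
        ) from err
    df = summaries.copy()
    df["group"] = df["participant"].map(groups)
    table = pg.mixed_anova(
        data=df,
        dv=measure,
        within="condition",
        between="group",
        subject="participant",
        correction=True,
    )
    table["delegated"] = True
    return table


# ---------------------------------------------------------------------------
# end-to-end run


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    coherence_config: CoherenceConfig = CoherenceConfig(),
    with_plots: bool = True,
    with_delegated_stats: bool = False,
) -> Path:
    """Run the full analysis over a dataset directory.

    The directory must follow the layout written by
    :func:`synchrolab.synthetic.simulate_cohort` (tap log, response log,
    onset files, optional EEG).  Outputs TSV tables, optional figures and
    a run manifest into ``out_dir``.
    """
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taps_path = data / "taps.tsv"
    resp_path = data / "responses.tsv"
    stim_dir = data / "stimuli"
    for p in (taps_path, resp_path, stim_dir):
        if not p.exists():
            raise FileNotFoundError(f"dataset incomplete: missing {p}")

    sequences = {
        p.stem: read_onsets(p) for p in sorted(stim_dir.glob("*.tsv"))
    }
    if not sequences:
        raise ValueError(f"no onset files in {stim_dir}")
    trains, groups = tapping.read_tap_log(taps_path)
    summaries = participant_summaries(trains, sequences)
    sync_table = build_sync_table(summaries, groups)

    responses = pd.read_csv(resp_path, sep="\t", dtype={"participant": str})
    coded = code_condition_responses(responses)
    response_table = build_response_table(coded)

    summaries.to_csv(out / "participant_summaries.tsv", sep="\t", index=False)
    sync_table.to_csv(out / "sync_table.tsv", sep="\t", index=False)
    response_table.to_csv(out / "response_table.tsv", sep="\t", index=False)

    eeg_dir = data / "eeg"
    manifest: dict = {
        "inputs": {
            "taps": _hash_file(taps_path),
            "responses": _hash_file(resp_path),
        },
        "coherence": None,
    }
    if eeg_dir.is_dir() and any(eeg_dir.glob("*_events.tsv")):
        per_participant: dict[tuple[str, str], eeg_mod.MaskedDifference] = {}
        link_frames = []
        run_files: dict[tuple[str, str], list[Path]] = {}
        for events_path in sorted(eeg_dir.glob("*_events.tsv")):
            stem = events_path.name[: -len("_events.tsv")]
            pid, cond, _run = stem.rsplit("_", 2)
            run_files.setdefault((pid, cond), []).append(events_path)
        for (pid, cond), event_paths in sorted(run_files.items()):
            task_runs = []
            sfreq, labels = eeg_mod.DEFAULT_SFREQ, None
            for run_idx, events_path in enumerate(event_paths, start=1):
                stem = events_path.name[: -len("_events.tsv")]
                task_data, sfreq, labels = eeg_mod.load_edf(eeg_dir / f"{stem}.edf")
                tap_ms = pd.read_csv(events_path, sep="\t")["tap_ms"].to_numpy()
                # lock epochs to cleaned taps only (warm-up, doubles, outliers)
                cleaned = tapping.clean(
                    tapping.TapTrain(pid, cond, run_idx, np.sort(tap_ms)),
                    sequences[cond],
                )
                task_runs.append((task_data, cleaned.valid_taps))
            rest_data, _, _ = eeg_mod.load_edf(eeg_dir / f"{pid}_rest.edf")
            masked = participant_coherence(
                task_runs, rest_data, sfreq, labels, coherence_config
            )
            per_participant[(pid, cond)] = masked
            frame = masked.to_frame()
            frame.insert(0, "participant", pid)
            frame.insert(1, "condition", cond)
            link_frames.append(frame)
        pd.concat(link_frames).to_csv(out / "link_coherence.tsv", sep="\t", index=False)
        net_table = network_table(per_participant, groups)
        net_table.to_csv(out / "network_differences.tsv", sep="\t", index=False)
        manifest["coherence"] = {
            "band": list(coherence_config.band),
            "alpha": coherence_config.alpha,
            "n_recordings": len(link_frames),
        }
        if with_plots:
            for grp in sorted(set(groups.values())):
                for cond in sorted({c for _, c in per_participant}):
                    members = [
                        m
                        for (pid, c), m in per_participant.items()
                        if groups[pid] == grp and c == cond
                    ]
                    if members:
                        plot_difference_matrix(
                            eeg_mod.group_average_mask(members),
                            out / f"diff_matrix_{grp}_{cond}.png",
                            title=f"{grp} / {cond}",
                        )
    if with_delegated_stats:
        delegated_mixed_anova(summaries, groups).to_csv(
            out / "delegated_anova_sd_se.tsv", sep="\t", index=False
        )
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
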