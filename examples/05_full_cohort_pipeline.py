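"""Simulate a small synthetic cohort and run the full analysis pipeline.

Builds a reduced three-group cohort (2 participants per group to keep the
example quick; the study-scale default is 9/11/12), writes tap logs,
verbal-response logs and task/rest EEG (EDF) to disk, then runs the
pipeline: cleaning and synchronization summaries, verbal-response coding,
tap-locked coherence with rest subtraction, KS masking and network
aggregation, ending in study-shaped tables.
"""

import tempfile
from pathlib import Path

import pandas as pd

from synchrolab import run_pipeline
from synchrolab.synthetic import CohortSpec, simulate_cohort

workdir = Path(tempfile.mkdtemp(prefix="synchrolab_"))
spec = CohortSpec(group_sizes={"DCD": 2, "TD": 2, "TDM": 2}, seed=7)
data = simulate_cohort(spec, workdir / "data")
print(f"dataset written to {data}")

out = run_pipeline(data, workdir / "out", with_plots=False)

sync = pd.read_csv(out / "sync_table.tsv", sep="\t")
print("\nsynchronization variability (SD of SE, ms) by group x condition:")
print(
    sync[sync.measure == "sd_se"]
    .set_index("condition")[["DCD_mean", "TD_mean", "TDM_mean"]]
    .round(1)
)
print("(the DCD preset is the most variable; all groups destabilize at d20)")

resp = pd.read_csv(out / "response_table.tsv", sep="\t")
print("\npercent correct verbal reports:")
print(resp)
print("(everyone detects the 20% perturbation; the 3% change goes unnoticed)")

nets = pd.read_csv(out / "network_differences.tsv", sep="\t")
print("\nmasked coherence differences by network:")
print(nets.round(3))
print("(interhemispheric coupling rises at d20 for the TD groups only)")
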