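"""Tap-locked beta-band coherence with resting-state subtraction.

Synthesizes one participant's 32-channel EEG with strong planted
interhemispheric beta coupling during the task and baseline coupling at
rest, epochs the task recording around the taps (-100..+500 ms, baseline
corrected over -500..-300 ms), computes Morlet-wavelet coherence
(12-30 Hz, one cycle) per fronto-central link, masks task-minus-rest
differences with the two-sample KS test at p < 0.01, and averages the
surviving differences within the three link groups.
"""

import numpy as np

from synchrolab import aggregate_networks, epoch_rest, epoch_task, ks_mask, wavelet_coherence
from synchrolab.eeg import TASK_WINDOW, network_links
from synchrolab.synthetic import MONTAGE_32, simulate_eeg

# one run: taps every 1250 ms for 75 s, after a 2 s lead-in
taps_ms = 2000.0 + np.arange(60) * 1250.0
coupling = {"intrahemispheric": 0.3, "midline": 0.3, "interhemispheric": 1.0}
task = simulate_eeg(coupling, duration_s=78.0, tap_times_ms=taps_ms, seed=11)
rest = simulate_eeg({k: 0.3 for k in coupling}, duration_s=30.0, seed=12)

task_ep = epoch_task(task, 250.0, taps_ms, MONTAGE_32).connectivity_view()
rest_ep = epoch_rest(rest, 250.0, TASK_WINDOW[1] - TASK_WINDOW[0], MONTAGE_32)
rest_ep = rest_ep.connectivity_view()
print(f"task epochs: {task_ep.n_epochs} x {task_ep.n_samples} samples; "
      f"rest epochs: {rest_ep.n_epochs}")

links = network_links()
task_coh = wavelet_coherence(task_ep, links=links)
rest_coh = wavelet_coherence(rest_ep, links=links)
masked = ks_mask(task_coh, rest_coh, alpha=0.01)

print("\nlink        task   rest   masked diff")
for i, (a, b) in enumerate(masked.links):
    print(f"{a}-{b:<6} {masked.task_mean[i]:.3f}  {masked.rest_mean[i]:.3f}  "
          f"{masked.difference[i]:+.3f}")

nets = aggregate_networks(masked)
print("\nnetwork means (task - rest, masked):")
for name, val in nets.items():
    print(f"  {name:<18} {val:+.3f}")
print("\nthe planted interhemispheric coupling survives the mask; the "
      "unchanged networks are zeroed by the KS test")
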