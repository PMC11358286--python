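"""Run the 2-up-1-down adaptive staircase against a simulated listener.

Two successive correct responses make the task harder (smaller stimulus
deviation), one error makes it easier; the procedure converges on the
level answered correctly 70.7% of the time.  The threshold estimate is
the mean level at the last six reversals of a 43-trial track.
"""

import numpy as np

from synchrolab import ObserverModel, estimate_threshold, run_simulated_staircase
from synchrolab.psychophysics import CONVERGENCE_P

observer = ObserverModel(threshold=20.0, slope=2.0, lapse_rate=0.02)
print(f"observer 70.7%-correct level: {observer.level_at(CONVERGENCE_P):.2f}")

track = run_simulated_staircase(observer, n_trials=43, seed=3)
print(f"levels visited (first 15): {[f'{l:g}' for l in track.levels[:15]]}")
print(f"reversals at trials {track.reversals}")
print(f"single-track threshold estimate: {estimate_threshold(track):.2f}")

ests = [
    estimate_threshold(run_simulated_staircase(observer, 43, seed=s))
    for s in range(200)
]
print(
    f"mean estimate over 200 tracks: {np.mean(ests):.2f} "
    f"(SD {np.std(ests):.2f}) -- concentrates at the 70.7% level"
)
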