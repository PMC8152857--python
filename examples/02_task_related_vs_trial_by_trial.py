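"""Task-related vs. trial-by-trial correlation for one pair.

The task-related analysis pools 300 ms windows across all trial epochs, so
shared task modulation (beta falls after the cue while the rate rises) can
produce a strong negative correlation even without any intrinsic coupling.
The trial-by-trial analysis holds the epoch fixed (pre-SC) and correlates
across trials, isolating intrinsic covariation — for a null pair it should
hover near zero.
"""

import numpy as np

from betacorr import GeneratorConfig, TaskTiming, generate_pair, prepare_pair
from betacorr import task_related_correlation, trial_by_trial_correlation

cfg = GeneratorConfig(n_trials_per_condition=20)  # 6 directions, coupling_c=0
timing = TaskTiming.monkey_t()
pair = generate_pair(cfg, timing, 0, np.random.SeedSequence(2))
prepared = prepare_pair(pair, band_center=22.0)

print(f"preferred direction: {prepared.pref_direction} "
      f"(ground truth {prepared.ground_truth['pref_direction']})")

rng = np.random.default_rng(0)
task = task_related_correlation(prepared, "preferred", "short", rng)
print(f"\ntask-related (preferred, short): rho = {task.rho:+.3f}, "
      f"p = {task.p:.2e}, n = {task.n} windows")

tbt = trial_by_trial_correlation(prepared, "pre_SC", "short", rng)
print(f"trial-by-trial (pre-SC, short):  rho = {tbt.rho:+.3f}, "
      f"p = {tbt.p:.3f}, n = {tbt.n} trials")

print("\nThe task-related rho is typically clearly negative (concurrent but"
      "\nindependent task modulation of both signals); the trial-by-trial rho"
      "\nis near zero because this pair has no intrinsic coupling.")
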