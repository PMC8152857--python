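"""The trial-shuffling control: does a correlation survive?

Pairing the beta envelope of trial π(i) with the spike counts of trial i
destroys any fine within-trial relationship but preserves task-locked
modulation.  A task-co-modulated null pair does NOT survive (its shuffled
correlations are as strong as the observed one); a pair with injected
intrinsic coupling does.
"""

import numpy as np

from betacorr import GeneratorConfig, TaskTiming, generate_pair, prepare_pair
from betacorr import task_related_correlation, trial_shuffle_correlation

timing = TaskTiming.monkey_t()

for label, c in (("null (coupling_c = 0)", 0.0),
                 ("intrinsically coupled (coupling_c = 1)", 1.0)):
    cfg = GeneratorConfig(n_trials_per_condition=20, directions=(1, 4),
                          delay_classes=("short",), coupling_c=c)
    pair = generate_pair(cfg, timing, 0, np.random.SeedSequence(4))
    prepared = prepare_pair(pair, 22.0)
    rng = np.random.default_rng(1)
    obs = task_related_correlation(prepared, "preferred", "short", rng)
    out = trial_shuffle_correlation(prepared, "preferred", "short",
                                    n_reps=1000, rng=rng,
                                    rho_observed=obs.rho)
    q99 = np.quantile(np.abs(out.shuffled_rhos), 0.99)
    print(f"{label}:")
    print(f"  observed rho = {obs.rho:+.3f}; shuffled |rho| 99th pct = {q99:.3f}")
    print(f"  shuffles with |rho| >= observed: {out.exceed_count}/1000 "
          f"-> survives: {out.survives}\n")

print("Only the intrinsically coupled pair beats 990/1000 shuffles: the"
      "\nnull pair's correlation is fully explained by task co-modulation.")
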