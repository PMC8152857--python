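"""Spike-to-beta phase locking with a trial-shuffle null.

A unit that locks to the beta rhythm fires preferentially at a particular
oscillation phase.  Locking is quantified in delay D1 of long trials with
the Rayleigh statistic z = n·R² and judged against 1000 recombinations of
phases and spikes from different trials.
"""

import numpy as np

from betacorr import GeneratorConfig, TaskTiming, generate_pair, prepare_pair
from betacorr import phase_lock_significance, spike_phases
from betacorr.phase_locking import circular_mean

timing = TaskTiming.monkey_t()

for label, m in (("unlocked unit (m = 0)", 0.0), ("locked unit (m = 0.5)", 0.5)):
    cfg = GeneratorConfig(n_trials_per_condition=10, directions=(1, 4),
                          delay_classes=("long",), locking_m=m,
                          locking_phase=np.pi / 2)
    pair = generate_pair(cfg, timing, 0, np.random.SeedSequence(9))
    prepared = prepare_pair(pair, 22.0)
    res = phase_lock_significance(prepared, n_reps=1000,
                                  rng=np.random.default_rng(2))
    print(f"{label}: n = {res.n_spikes} D1 spikes")
    print(f"  R = {res.resultant_R:.3f}, z = {res.rayleigh_z:.1f}, "
          f"Rayleigh p = {res.p_rayleigh:.2e}")
    if m > 0:
        ph = spike_phases(prepared, "long")
        print(f"  circular mean phase = {circular_mean(ph):+.2f} rad "
              f"(injected +{np.pi/2:.2f})")
    print(f"  shuffles with z >= observed: {res.shuffle_exceed_count}/1000 "
          f"-> significant: {res.significant}\n")

print("The locked unit concentrates its spikes near the injected phase and"
      "\nbeats the shuffle null; the unlocked unit does not.")
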