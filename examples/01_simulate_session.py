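"""Generate a small synthetic session and look at its structure.

A session holds beta-neuron pairs; each pair has per-trial task events, a
1 kHz LFP trace with beta bursts, and a spike train of one unit.  Here the
ground truth says coupling_c = 0: beyond shared task modulation, the unit's
rate is independent of the beta envelope.
"""

import numpy as np

from betacorr import GeneratorConfig, TaskTiming, generate_session
from betacorr import bandpass_filter, analytic_envelope_phase

cfg = GeneratorConfig(n_trials_per_condition=10, directions=(1, 4))
timing = TaskTiming.monkey_t()
session = generate_session(cfg, timing, n_pairs=2, seed=1)

pair = session.pairs[0]
print(f"pairs: {len(session.pairs)}, trials per pair: {len(pair.events)}")
print(f"ground truth: {pair.ground_truth}")

ev = pair.events[0]
print(f"\ntrial {ev.trial_id}: direction {ev.direction}, {ev.delay_class} delay")
print(f"  TC on {ev.t_tc_on:.0f} ms, SC on {ev.t_sc_on:.0f} ms, "
      f"GO {ev.t_go:.0f} ms, movement {ev.t_move_on:.0f} ms")

lfp = pair.lfps[ev.trial_id]
env = analytic_envelope_phase(bandpass_filter(lfp, 22.0), 22.0)
i_sc = int(ev.t_sc_on)
i_mv = int(ev.t_move_on)
print(f"\nLFP: {len(lfp)} samples at {lfp.fs:.0f} Hz")
print(f"mean beta envelope pre-SC:        {env.amplitude[i_sc-300:i_sc].mean():.2f} a.u.")
print(f"mean beta envelope post-movement: {env.amplitude[i_mv:i_mv+300].mean():.2f} a.u.")
print("(beta is suppressed around movement: event-related desynchronization)")
print(f"\nunit: {len(pair.spikes[ev.trial_id])} spikes in this trial")
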