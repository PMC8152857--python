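"""Windowing, epochs, preferred direction, inclusion, subsampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from betacorr.core import (EnvelopeTrace, SpikeTrain, TaskTiming, TrialEvents)
from betacorr.segmentation import (cut_windows, extract_epoch,
                                   preferred_direction, rate_inclusion,
                                   subsample_positions_batch,
                                   subsample_windows)
from betacorr.synthetic_data import (GeneratorConfig, generate_spike_train,
                                     generate_trial_events)


def _flat_env(n):
    return EnvelopeTrace(np.ones(n), np.zeros(n), 1000.0, 0.0, 22.0, 5.0)


def _events(timing, delay_class, rng=None, direction=1):
    rng = rng or np.random.default_rng(0)
    return generate_trial_events(timing, direction, delay_class, rng)


@pytest.mark.parametrize("timing,delay_class,expected", [
    (TaskTiming.monkey_t(), "short", 11),
    (TaskTiming.monkey_t(), "long", 16),
    (TaskTiming.monkey_m(), "short", 13),
    (TaskTiming.monkey_m(), "long", 19),
])
def test_window_counts_for_both_task_timings(timing, delay_class, expected):
    """300 ms tiling of [start, GO + 1000 ms) gives 11/16 windows for the
    short/long monkey-T timing and 13/19 for monkey-M."""
    ev = _events(timing, delay_class)
    n = int(round(timing.analysis_span(delay_class)))
    wins = cut_windows(ev, _flat_env(n), SpikeTrain(0, np.empty(0)))
    assert len(wins) == expected
    # tiling: consecutive, non-overlapping, from 0
    assert wins[0].t_start == 0.0
    assert all(w2.t_start == w1.t_end for w1, w2 in zip(wins, wins[1:]))
    assert all(w.t_end - w.t_start == 300.0 for w in wins)


def test_partial_final_window_discarded():
    ev = TrialEvents(0, 1, "short", 0.0, 10.0, 20.0, 50.0, 60.0, 120.0, 150.0)
    wins = cut_windows(ev, _flat_env(1000), SpikeTrain(0, np.empty(0)),
                       post_go_ms=179.0)   # span 299 ms -> 0 windows
    assert wins == []


def test_spike_conservation_across_windows(rng, timing_t):
    """Sum of per-window counts equals the spike count in the tiled span."""
    ev = _events(timing_t, "short")
    n = int(timing_t.analysis_span("short"))
    spikes = SpikeTrain(0, np.sort(rng.uniform(0, n, 400)))
    wins = cut_windows(ev, _flat_env(n), spikes)
    tiled_end = 300.0 * len(wins)
    assert sum(w.spike_count for w in wins) == spikes.count_in(0.0, tiled_end)


def test_epoch_windows_and_half_open_convention(timing_t):
    """Pre-SC epoch is [1300, 1600) and pre-TC [400, 700) for the monkey-T
    short timing; a spike exactly at SC onset is excluded."""
    ev = _events(timing_t, "short")
    n = int(timing_t.analysis_span("short"))
    spikes = SpikeTrain(0, np.array([1300.0, 1600.0]))
    pre_sc = extract_epoch(ev, _flat_env(n), spikes, "pre_SC")
    assert (pre_sc.t_start, pre_sc.t_end) == (1300.0, 1600.0)
    assert pre_sc.spike_count == 1     # left edge in, spike at exactly 1600 out
    pre_tc = extract_epoch(ev, _flat_env(n), spikes, "pre_TC")
    assert (pre_tc.t_start, pre_tc.t_end) == (400.0, 700.0)
    with pytest.raises(ValueError):
        extract_epoch(ev, _flat_env(n), spikes, "pre_GO")


def test_epoch_before_trial_start_rejected():
    ev = TrialEvents(0, 1, "short", 0.0, 200.0, 240.0, 500.0, 510.0, 800.0, 900.0)
    with pytest.raises(ValueError):
        extract_epoch(ev, _flat_env(2000), SpikeTrain(0, np.empty(0)), "pre_TC")


def test_preferred_direction_recovers_ground_truth(timing_t):
    """With strong cosine tuning, the empirical preferred direction matches
    the generator's in nearly all units."""
    hits = 0
    n_units = 60
    for u in range(n_units):
        rng = np.random.default_rng(100 + u)
        cfg = GeneratorConfig(tuning_depth=0.8, pref_direction=3,
                              base_rate=12.0)
        trials = []
        for d in range(1, 7):
            for _ in range(50):
                ev = generate_trial_events(timing_t, d, "short", rng,
                                           trial_id=len(trials))
                st_ = generate_spike_train(ev, cfg, None, rng,
                                           timing_t.analysis_span("short"))
                trials.append((ev, st_))
        pref, nonpref = preferred_direction(trials)
        hits += (pref == 3)
        if pref == 3:
            assert nonpref == 6
    assert hits >= 0.95 * n_units


def test_preferred_direction_tie_breaks_to_lowest_index(timing_t):
    ev_proto = _events(timing_t, "short")
    spikes = np.arange(1700.0, 3000.0, 50.0)   # identical post-SC activity
    trials = []
    for d in range(1, 7):
        ev = TrialEvents(d, d, "short", *[getattr(ev_proto, f) for f in
                         ("t_start", "t_tc_on", "t_tc_off", "t_sc_on",
                          "t_sc_off", "t_go", "t_move_on")])
        trials.append((ev, SpikeTrain(d, spikes.copy())))
    pref, nonpref = preferred_direction(trials)
    assert (pref, nonpref) == (1, 4)


def test_preferred_direction_two_direction_session(timing_t):
    """In an opposite-pair session the higher-rate member wins."""
    ev_proto = _events(timing_t, "short")
    fields = [getattr(ev_proto, f) for f in
              ("t_start", "t_tc_on", "t_tc_off", "t_sc_on", "t_sc_off",
               "t_go", "t_move_on")]
    dense = np.arange(1700.0, 3000.0, 20.0)
    sparse = np.arange(1700.0, 3000.0, 200.0)
    trials = [(TrialEvents(0, 5, "short", *fields), SpikeTrain(0, dense)),
              (TrialEvents(1, 2, "short", *fields), SpikeTrain(1, sparse))]
    pref, nonpref = preferred_direction(trials)
    assert (pref, nonpref) == (5, 2)


def test_rate_inclusion_strict_threshold():
    class S:
        def __init__(self, c):
            self.spike_count = c

    assert not rate_inclusion([S(0.9)] * 10)        # exactly 3.0 Hz -> excluded
    assert rate_inclusion([S(1.2)] * 10)            # 4 Hz -> included
    assert not rate_inclusion([S(0)] * 10)
    with pytest.raises(ValueError):
        rate_inclusion([])


def test_subsample_exact_halving(rng):
    wins = list(range(20))
    assert subsample_windows(wins, 10, rng) == list(range(0, 20, 2))
    assert subsample_windows(wins, 20, rng) == wins
    with pytest.raises(ValueError):
        subsample_windows(wins, 21, rng)


def test_subsample_with_random_reintroduction(rng):
    """20 windows to target 7: two halving rounds leave {0,4,8,12,16}, then
    2 windows are reintroduced from the excluded 15."""
    wins = list(range(20))
    out = subsample_windows(wins, 7, rng)
    assert len(out) == 7
    assert set([0, 4, 8, 12, 16]).issubset(out)
    assert out == sorted(out)
    assert set(out).issubset(wins)


@given(st.integers(min_value=1, max_value=60), st.data())
def test_subsample_is_ordered_subset(n, data):
    target = data.draw(st.integers(min_value=0, max_value=n))
    rng = np.random.default_rng(7)
    wins = list(range(n))
    out = subsample_windows(wins, target, rng)
    assert len(out) == target
    assert out == sorted(set(out))
    assert set(out).issubset(wins)
    # deterministic given the seed
    out2 = subsample_windows(wins, target, np.random.default_rng(7))
    assert out == out2


def test_batch_subsample_matches_scheme(rng):
    sel = subsample_positions_batch(20, 7, rng, n_draws=50)
    assert sel.shape == (50, 7)
    for row in sel:
        assert set([0, 4, 8, 12, 16]).issubset(row)
        assert len(set(row.tolist())) == 7
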