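"""Generator: event timing, point-process calibration, burst statistics."""

import numpy as np
import pytest
from scipy import stats

from betacorr.core import EPOCHS, EnvelopeTrace, TaskTiming
from betacorr.signal_processing import analytic_envelope_phase, bandpass_filter
from betacorr.synthetic_data import (GeneratorConfig,
                                     draw_burst_onsets_durations,
                                     generate_lfp, generate_pair,
                                     generate_session, generate_spike_train,
                                     generate_trial_events, one_over_f_noise)

FLAT_RATE = {e: 1.0 for e in EPOCHS}


def test_event_times_follow_task_timing_exactly(rng):
    """Monkey-T short-delay trials: TC at 700 ms, SC at 1600 ms, GO at
    2355 ms (700 + 200 + 700 + 55 + 700)."""
    ev = generate_trial_events(TaskTiming.monkey_t(), 1, "short", rng)
    assert ev.t_tc_on == 700
    assert ev.t_tc_off == 900
    assert ev.t_sc_on == 1600
    assert ev.t_sc_off == 1655
    assert ev.t_go == 2355
    ev_long = generate_trial_events(TaskTiming.monkey_t(), 1, "long", rng)
    assert ev_long.t_go == 700 + 200 + 1500 + 55 + 1500
    ev_m = generate_trial_events(TaskTiming.monkey_m(), 1, "short", rng)
    assert ev_m.t_go == 700 + 200 + 1000 + 55 + 1000


def test_reaction_time_degenerate_and_bounded(rng):
    timing = TaskTiming(rt_mean=160.0, rt_sd=0.0)
    ev = generate_trial_events(timing, 2, "short", rng)
    assert ev.t_move_on == ev.t_go + 160.0
    timing = TaskTiming(rt_mean=400.0, rt_sd=150.0)
    rts = [generate_trial_events(timing, 2, "short", rng).t_move_on - timing.go_time("short")
           for _ in range(1000)]
    assert all(0 < rt <= 500.0 for rt in rts)


def test_invalid_inputs_rejected(rng, timing_t):
    with pytest.raises(ValueError):
        generate_trial_events(timing_t, 7, "short", rng)
    with pytest.raises(ValueError):
        generate_trial_events(timing_t, 1, "medium", rng)
    with pytest.raises(ValueError):
        GeneratorConfig(tuning_depth=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(burst_dur_range=(500.0, 200.0))
    with pytest.raises(ValueError):
        generate_pair(GeneratorConfig(n_trials_per_condition=5), timing_t, 0,
                      np.random.SeedSequence(0))
    with pytest.raises(ValueError):
        generate_session(GeneratorConfig(), timing_t, 0, seed=0)
    ev = generate_trial_events(timing_t, 1, "short", rng)
    with pytest.raises(ValueError):
        generate_spike_train(ev, GeneratorConfig(coupling_c=0.5), None, rng)


def test_session_determinism_and_arithmetic(timing_t):
    """Same (cfg, seed) must give bit-identical sessions; trial count is
    n_trials_per_condition x directions x delay classes; ground-truth labels
    propagate to every pair."""
    cfg = GeneratorConfig(n_trials_per_condition=8, directions=(2, 5))
    s1 = generate_session(cfg, timing_t, 2, seed=11)
    s2 = generate_session(cfg, timing_t, 2, seed=11)
    for p1, p2 in zip(s1.pairs, s2.pairs):
        assert p1.ground_truth == p2.ground_truth
        assert p1.ground_truth["coupling_c"] == 0.0
        for ev1, ev2 in zip(p1.events, p2.events):
            assert ev1 == ev2
        for tid in p1.lfps:
            np.testing.assert_array_equal(p1.lfps[tid].samples,
                                          p2.lfps[tid].samples)
            np.testing.assert_array_equal(p1.spikes[tid].spike_times,
                                          p2.spikes[tid].spike_times)
    assert len(s1.pairs[0].events) == 8 * 2 * 2
    cfg6 = GeneratorConfig(n_trials_per_condition=20)
    # 20 trials x 6 directions x 2 delays = 240 trials (checked without generating)
    assert 20 * len(cfg6.directions) * len(cfg6.delay_classes) == 240


def test_homogeneous_poisson_rate_calibration(rng, timing_t):
    """With flat profiles and no tuning the train is homogeneous Poisson;
    the realized rate over many trials must match the requested 20 Hz."""
    cfg = GeneratorConfig(base_rate=20.0, rate_profile=FLAT_RATE,
                          tuning_depth=0.0)
    ev = generate_trial_events(timing_t, 1, "short", rng)
    dur = timing_t.analysis_span("short")
    counts = [len(generate_spike_train(ev, cfg, None, rng, dur))
              for _ in range(600)]
    rate = np.mean(counts) / (dur / 1000.0)
    assert 19.0 <= rate <= 21.0


def test_rate_profile_calibration_per_epoch(rng, timing_t):
    """Realized mean rate per epoch within 5% of the intensity integrated
    over that epoch, across many trials."""
    cfg = GeneratorConfig(base_rate=15.0, tuning_depth=0.0)
    timing = TaskTiming(rt_sd=0.0)  # fixed epochs across trials
    ev = generate_trial_events(timing, 1, "short", rng)
    dur = timing.analysis_span("short")
    edges = ev.epoch_edges(dur)
    n_trials = 500
    counts = np.zeros(len(EPOCHS))
    for _ in range(n_trials):
        st = generate_spike_train(ev, cfg, None, rng, dur)
        hist, _ = np.histogram(st.spike_times, bins=edges)
        counts += hist
    for k, epoch in enumerate(EPOCHS):
        dur_s = (edges[k + 1] - edges[k]) / 1000.0
        expected = cfg.base_rate * cfg.rate_profile[epoch] * dur_s * n_trials
        assert abs(counts[k] - expected) / expected < 0.05, epoch


def test_base_rate_zero_gives_empty_train(rng, timing_t):
    ev = generate_trial_events(timing_t, 1, "short", rng)
    st = generate_spike_train(ev, GeneratorConfig(base_rate=0.0), None, rng)
    assert len(st) == 0


def test_burst_durations_uniform(rng, timing_t):
    """Empirical burst durations are uniform on burst_dur_range."""
    cfg = GeneratorConfig()
    ev = generate_trial_events(timing_t, 1, "short", rng)
    durs = []
    while len(durs) < 1000:
        _, d = draw_burst_onsets_durations(ev, cfg, 3355.0, rng)
        durs.extend(d.tolist())
    lo, hi = cfg.burst_dur_range
    p = stats.kstest(np.array(durs[:1000]), stats.uniform(lo, hi - lo).cdf).pvalue
    assert p > 0.01


def test_zero_burst_amplitude_reduces_to_noise(rng, timing_t):
    """With burst_amp = 0 the beta-band power of the trace equals that of
    pure 1/f noise (no residual oscillatory component)."""
    cfg = GeneratorConfig(burst_amp=0.0)
    ev = generate_trial_events(timing_t, 1, "short", rng)

    def band_var(x):
        from betacorr.core import AnalogTrace
        f = bandpass_filter(AnalogTrace(x), 22.0)
        return f.samples.var()

    v_trace = np.mean([band_var(generate_lfp(ev, cfg, rng).samples)
                       for _ in range(60)])
    v_noise = np.mean([band_var(one_over_f_noise(3355, 1.0, 1.0, rng))
                       for _ in range(60)])
    assert 0.8 < v_trace / v_noise < 1.25


def test_envelope_suppressed_after_movement_onset(rng, timing_t):
    """The default burst-probability profile emulates movement-related beta
    suppression: trial-averaged envelope in the 300 ms after movement onset
    is well below the pre-SC epoch level."""
    cfg = GeneratorConfig()
    post, pre = [], []
    for _ in range(200):
        ev = generate_trial_events(timing_t, 1, "short", rng)
        dur = timing_t.analysis_span("short")
        lfp = generate_lfp(ev, cfg, rng, dur)
        env = analytic_envelope_phase(bandpass_filter(lfp, 22.0), 22.0)
        i_mv = int(ev.t_move_on)
        post.append(env.amplitude[i_mv:i_mv + 300].mean())
        i_sc = int(ev.t_sc_on)
        pre.append(env.amplitude[i_sc - 300:i_sc].mean())
    assert np.mean(post) < 0.6 * np.mean(pre)


def test_spectral_peak_at_band_center(rng, timing_t):
    """The periodogram of concatenated trials peaks within 1 Hz of the
    configured 22 Hz band center (above the 1/f drift range)."""
    cfg = GeneratorConfig()
    ev = generate_trial_events(timing_t, 1, "short", rng)
    sig = np.concatenate([generate_lfp(ev, cfg, rng).samples
                          for _ in range(100)])
    n = sig.size
    spec = np.abs(np.fft.rfft(sig * np.hanning(n))) ** 2
    freqs = np.fft.rfftfreq(n, d=1e-3)
    band = (freqs >= 5.0) & (freqs <= 100.0)
    peak = freqs[band][np.argmax(spec[band])]
    assert abs(peak - 22.0) <= 1.0


def test_locking_resultant_length_calibration(rng, timing_t):
    """Spike phases under rate ∝ 1 + m·cos(φ) have mean resultant length
    m/2 (analytic integral of the biased density): m = 0.5 → R = 0.25."""
    m = 0.5
    cfg = GeneratorConfig(base_rate=100.0, rate_profile=FLAT_RATE,
                          tuning_depth=0.0, locking_m=m, locking_phase=0.0)
    ev = generate_trial_events(timing_t, 1, "short", rng)
    dur = timing_t.analysis_span("short")
    n = int(dur)
    t = np.arange(n) / 1000.0
    phase = np.angle(np.exp(1j * 2 * np.pi * 22.0 * t))
    env = EnvelopeTrace(np.ones(n), phase, 1000.0, 0.0, 22.0, 5.0)
    phases = []
    while len(phases) < 100_000:
        st = generate_spike_train(ev, cfg, env, rng, dur)
        idx = np.minimum(st.spike_times.astype(int), n - 1)
        phases.extend(phase[idx].tolist())
    R = np.abs(np.exp(1j * np.array(phases[:100_000])).mean())
    assert abs(R - m / 2.0) < 0.02
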