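"""Task-structured synthetic sessions with known ground truth.

Real sessions of this kind are not publicly deposited, so analyses are
exercised on surrogate data that emulates their statistical structure:

* **LFP** — 1/f background noise plus beta bursts: Hanning-windowed
  sinusoids at the band center, 200–500 ms long, whose onsets follow a
  Poisson process with epoch-dependent intensity (suppressed after the
  spatial cue and strongest suppression around movement, emulating
  event-related desynchronization).  Burst timing is otherwise not locked
  to task events.  A "monkey-M-like" configuration sums two independent
  burst processes (≈19 and ≈32 Hz) into one LFP.
* **Spikes** — an inhomogeneous Poisson process simulated by thinning,
  with intensity

  ``λ(t) = base_rate · rate_profile(epoch) · (1 + tuning_depth·cos(θ_dir − θ_pref))
  · (1 + coupling_c·Ã(t)) · (1 + locking_m·cos(φ(t) − locking_phase))``

  clipped at zero, where ``Ã`` is the z-scored beta envelope and ``φ`` the
  beta phase.  ``coupling_c`` and ``locking_m`` are ground-truth knobs: zero
  means the unit is genuinely independent of the beta signal apart from
  shared task modulation.

Each beta-neuron pair combines a unit with an LFP generated as a distinct
trace, emulating pairing across different electrodes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (DELAY_CLASSES, DIRECTIONS, EPOCHS, AnalogTrace,
                   EnvelopeTrace, Session, SessionPair, SpikeTrain,
                   TaskTiming, TrialEvents)
from . import signal_processing as sp

RT_MAX_MS = 500.0

#: Epoch multipliers for beta-burst probability.  High during the delays,
#: suppressed after the spatial cue, most strongly around movement.
DEFAULT_BURST_PROFILE: Dict[str, float] = {
    "pre_tc": 1.0, "tc": 1.0, "d1": 1.2, "sc": 0.9,
    "d2": 0.5, "post_go": 0.35, "move": 0.2,
}

#: Epoch multipliers for firing rate: phasic increase after the spatial cue,
#: sustained preparatory activity, strongest around movement execution.
DEFAULT_RATE_PROFILE: Dict[str, float] = {
    "pre_tc": 1.0, "tc": 1.0, "d1": 0.9, "sc": 1.1,
    "d2": 1.6, "post_go": 1.9, "move": 2.2,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic session generator.

    Defaults describe a monkey-T-like session: one ≈22 Hz beta band, six
    movement directions, 20 correct trials per condition.  ``coupling_c``
    and ``locking_m`` default to zero (no intrinsic envelope-to-rate
    relationship, no phase locking), which is the null the analyses are
    calibrated against.
    """

    n_trials_per_condition: int = 20
    beta_centers: Tuple[float, ...] = (22.0,)
    band_half_width: float = 5.0
    burst_rate: float = 2.0                  # bursts/s at profile multiplier 1
    burst_dur_range: Tuple[float, float] = (200.0, 500.0)
    burst_amp: float = 4.0                   # a.u., relative to noise_sigma
    burst_amp_jitter: Tuple[float, float] = (0.6, 1.4)
    burst_prob_profile: Mapping = field(default_factory=lambda: dict(DEFAULT_BURST_PROFILE))
    noise_exponent: float = 1.0
    noise_sigma: float = 1.0
    base_rate: float = 10.0                  # Hz
    rate_profile: Mapping = field(default_factory=lambda: dict(DEFAULT_RATE_PROFILE))
    tuning_depth: float = 0.5
    pref_direction: Optional[int] = None     # None -> drawn per pair
    coupling_c: float = 0.0
    locking_m: float = 0.0
    locking_phase: float = 0.0
    directions: Tuple[int, ...] = DIRECTIONS
    delay_classes: Tuple[str, ...] = DELAY_CLASSES

    def __post_init__(self) -> None:
        if not 0.0 <= self.tuning_depth <= 1.0:
            raise ValueError("tuning_depth must lie in [0, 1]")
        if not 0.0 <= self.locking_m <= 1.0:
            raise ValueError("locking_m must lie in [0, 1]")
        lo, hi = self.burst_dur_range
        if lo <= 0 or hi < lo:
            raise ValueError("burst_dur_range must be positive and ordered")
        if self.burst_rate < 0 or self.base_rate < 0:
            raise ValueError("rates must be non-negative")
        for d in self.directions:
            if d not in DIRECTIONS:
                raise ValueError(f"invalid direction {d}")
        for dc in self.delay_classes:
            if dc not in DELAY_CLASSES:
                raise ValueError(f"invalid delay class {dc!r}")
        if self.pref_direction is not None and self.pref_direction not in DIRECTIONS:
            raise ValueError("pref_direction must be in 1..6")

    @classmethod
    def monkey_m_like(cls, **kw) -> "GeneratorConfig":
        kw.setdefault("beta_centers", (19.0, 32.0))
        return cls(**kw)

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def _truncnorm_rt(mean: float, sd: float, rng: np.random.Generator,
                  upper: float = RT_MAX_MS) -> float:
    """Reaction time from a normal truncated to (0, upper] ms."""
    if sd == 0:
        if not 0 < mean <= upper:
            raise ValueError("degenerate RT outside (0, 500]")
        return float(mean)
    for _ in range(1000):
        rt = rng.normal(mean, sd)
        if 0 < rt <= upper:
            return float(rt)
    raise RuntimeError("reaction-time sampling failed to converge")


def generate_trial_events(timing: TaskTiming, direction: int, delay_class: str,
                          rng: np.random.Generator, trial_id: int = 0) -> TrialEvents:
    """Event times of one trial: fixed epochs follow the timing exactly,
    movement onset is GO plus a truncated-normal reaction time."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be in 1..6, got {direction}")
    d = timing.delay(delay_class)
    t_tc_on = timing.start_to_tc
    t_tc_off = t_tc_on + timing.tc_dur
    t_sc_on = t_tc_off + d
    t_sc_off = t_sc_on + timing.sc_dur
    t_go = t_sc_off + d
    rt = _truncnorm_rt(timing.rt_mean, timing.rt_sd, rng)
    return TrialEvents(trial_id, direction, delay_class, 0.0, t_tc_on,
                       t_tc_off, t_sc_on, t_sc_off, t_go, t_go + rt)


def one_over_f_noise(n: int, exponent: float, sigma: float,
                     rng: np.random.Generator, fs: float = 1000.0) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise, scaled to the
    requested standard deviation.  Frequencies below 1 Hz are flattened to
    keep the variance finite."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(freqs, 1.0) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    if sd > 0:
        x *= sigma / sd
    return x


def draw_burst_onsets_durations(events: TrialEvents, cfg: GeneratorConfig,
                                duration_ms: float, rng: np.random.Generator,
                                lead_ms: float = 600.0
                                ) -> Tuple[np.ndarray, np.ndarray]:
    """Poisson burst onsets on [-lead, duration) with epoch-dependent
    intensity, plus per-burst durations uniform in ``burst_dur_range``.
    The lead-in lets bursts that started before trial start overlap it."""
    profile = np.array([cfg.burst_prob_profile[e] for e in EPOCHS])
    lam_max = cfg.burst_rate * profile.max() / 1000.0   # bursts per ms
    span = duration_ms + lead_ms
    n_cand = rng.poisson(lam_max * span)
    onsets = rng.uniform(-lead_ms, duration_ms, size=n_cand)
    durations = rng.uniform(*cfg.burst_dur_range, size=n_cand)
    accept_p = profile[events.epoch_of(np.maximum(onsets, 0.0), duration_ms)]
    keep = rng.random(n_cand) * profile.max() < accept_p
    return np.sort(onsets[keep]), durations[keep]


def generate_lfp(events: TrialEvents, cfg: GeneratorConfig,
                 rng: np.random.Generator,
                 duration_ms: Optional[float] = None) -> AnalogTrace:
    """One trial's LFP: 1/f noise plus Hanning-windowed beta bursts.

    Burst onsets follow a Poisson process whose intensity is
    ``burst_rate × burst_prob_profile(epoch of onset)``; bursts may overlap
    and add.  Beyond the per-epoch intensity, burst timing is not locked to
    the trial events.
    """
    fs = 1000.0
    if duration_ms is None:
        duration_ms = events.t_go + 1000.0
    n = int(round(duration_ms * fs / 1000.0))
    if n * 1000.0 / fs < events.t_go:
        raise ValueError("trace shorter than the analysis span")
    x = one_over_f_noise(n, cfg.noise_exponent, cfg.noise_sigma, rng, fs)
    lo_j, hi_j = cfg.burst_amp_jitter
    for center in cfg.beta_centers:
        onsets, durations = draw_burst_onsets_durations(events, cfg, duration_ms, rng)
        for onset, dur in zip(onsets, durations):
            amp = cfg.burst_amp * rng.uniform(lo_j, hi_j)
            phase0 = rng.uniform(0.0, 2.0 * np.pi)
            i0 = int(np.ceil(max(onset, 0.0) * fs / 1000.0))
            i1 = min(int(np.floor((onset + dur) * fs / 1000.0)), n)
            if i1 <= i0:
                continue
            t = np.arange(i0, i1) / fs * 1000.0   # ms
            rel = (t - onset) / dur               # position within the burst
            window = 0.5 - 0.5 * np.cos(2.0 * np.pi * rel)
            x[i0:i1] += amp * window * np.sin(2.0 * np.pi * center * t / 1000.0 + phase0)
    return AnalogTrace(x, fs=fs, t0=0.0)


def generate_spike_train(events: TrialEvents, cfg: GeneratorConfig,
                         beta_trace: Optional[EnvelopeTrace],
                         rng: np.random.Generator,
                         duration_ms: Optional[float] = None,
                         env_norm: Optional[Tuple[float, float]] = None
                         ) -> SpikeTrain:
    """Inhomogeneous Poisson spike train via thinning (exact for bounded λ).

    ``beta_trace`` must be supplied when ``coupling_c`` or ``locking_m`` is
    nonzero.  ``env_norm = (mean, sd)`` fixes the envelope z-scoring; when
    omitted, the supplied trace's own statistics are used (a session-level
    normalization is what makes injected trial-by-trial coupling coherent
    across trials — see generate_session).
    """
    if duration_ms is None:
        duration_ms = events.t_go + 1000.0
    n = int(round(duration_ms))
    needs_beta = cfg.coupling_c != 0.0 or cfg.locking_m != 0.0
    if needs_beta and beta_trace is None:
        raise ValueError("coupling or locking requested but no beta trace supplied")
    profile = np.array([cfg.rate_profile[e] for e in EPOCHS])
    t_grid = np.arange(n, dtype=float)
    lam = cfg.base_rate * profile[events.epoch_of(t_grid, duration_ms)]
    pref = cfg.pref_direction if cfg.pref_direction is not None else 1
    theta = 2.0 * np.pi * (events.direction - pref) / 6.0
    lam = lam * (1.0 + cfg.tuning_depth * np.cos(theta))
    if needs_beta:
        if len(beta_trace) < n:
            raise ValueError("beta trace does not cover the spike-train span")
        amp = beta_trace.amplitude[:n]
        if cfg.coupling_c != 0.0:
            if env_norm is None:
                mu, sd = float(amp.mean()), float(amp.std())
            else:
                mu, sd = env_norm
            a_z = (amp - mu) / sd if sd > 0 else np.zeros_like(amp)
            lam = lam * (1.0 + cfg.coupling_c * a_z)
        if cfg.locking_m != 0.0:
            lam = lam * (1.0 + cfg.locking_m
                         * np.cos(beta_trace.phase[:n] - cfg.locking_phase))
    lam = np.clip(lam, 0.0, None)
    if not np.all(np.isfinite(lam)):
        raise ValueError("intensity bound is not finite; check configuration")
    lam_max = float(lam.max())
    if lam_max == 0.0:
        return SpikeTrain(events.trial_id, np.empty(0))
    n_cand = rng.poisson(lam_max / 1000.0 * duration_ms)
    times = np.sort(rng.uniform(0.0, duration_ms, size=n_cand))
    accept = rng.random(n_cand) < lam[np.minimum(times.astype(int), n - 1)] / lam_max
    return SpikeTrain(events.trial_id, times[accept])


def generate_pair(cfg: GeneratorConfig, timing: TaskTiming, pair_id: int,
                  seed_seq: np.random.SeedSequence) -> SessionPair:
    """Generate one beta-neuron pair: per-trial events, LFP and spikes for
    every (direction × delay class) condition."""
    if cfg.n_trials_per_condition < 8:
        raise ValueError("at least 8 correct trials per condition are required")
    rng = np.random.default_rng(seed_seq)
    pref = (cfg.pref_direction if cfg.pref_direction is not None
            else int(rng.choice(cfg.directions)))
    cfg_pair = cfg.replace(pref_direction=pref)
    conditions = [(d, dc) for dc in cfg.delay_classes for d in cfg.directions
                  for _ in range(cfg.n_trials_per_condition)]
    order = rng.permutation(len(conditions))
    events_list = []
    for tid, k in enumerate(order):
        d, dc = conditions[k]
        events_list.append(generate_trial_events(timing, d, dc, rng, trial_id=tid))
    needs_beta = cfg.coupling_c != 0.0 or cfg.locking_m != 0.0
    lfps: Dict[int, AnalogTrace] = {}
    envs: Dict[int, EnvelopeTrace] = {}
    for ev in events_list:
        dur = timing.analysis_span(ev.delay_class)
        lfps[ev.trial_id] = generate_lfp(ev, cfg_pair, rng, dur)
        if needs_beta:
            filt = sp.bandpass_filter(lfps[ev.trial_id], cfg.beta_centers[0],
                                      cfg.band_half_width)
            envs[ev.trial_id] = sp.analytic_envelope_phase(
                filt, cfg.beta_centers[0], cfg.band_half_width)
    env_norm = None
    if cfg.coupling_c != 0.0:
        pooled = np.concatenate([envs[ev.trial_id].amplitude for ev in events_list])
        env_norm = (float(pooled.mean()), float(pooled.std()))
    spikes: Dict[int, SpikeTrain] = {}
    for ev in events_list:
        dur = timing.analysis_span(ev.delay_class)
        spikes[ev.trial_id] = generate_spike_train(
            ev, cfg_pair, envs.get(ev.trial_id), rng, dur, env_norm)
    ground_truth = {
        "coupling_c": cfg.coupling_c,
        "locking_m": cfg.locking_m,
        "locking_phase": cfg.locking_phase,
        "pref_direction": pref,
        "beta_centers": list(cfg.beta_centers),
    }
    return SessionPair(pair_id, events_list, lfps, spikes, ground_truth)


def generate_session(cfg: GeneratorConfig, timing: TaskTiming, n_pairs: int,
                     seed: int) -> Session:
    """A full synthetic session of ``n_pairs`` beta-neuron pairs.

    Each pair gets an independent child stream of the master seed, so the
    content of pair *k* does not depend on how many pairs are requested.
    Identical (cfg, timing, n_pairs, seed) yield bit-identical sessions.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_pairs)
    pairs = [generate_pair(cfg, timing, i, children[i]) for i in range(n_pairs)]
    return Session(pairs, timing, meta={"seed": seed, "n_pairs": n_pairs,
                                        "config": dataclasses.asdict(cfg)})
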