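"""Cutting trials into analysis windows and epochs.

The task-related analysis tiles each trial from the start (central touch)
until 1000 ms after GO with nonoverlapping, consecutive 300 ms windows; a
trailing partial window is discarded.  The trial-by-trial analysis uses one
fixed 300 ms epoch per trial, ending exactly at SC (or TC) onset.  Per
window/epoch we keep the mean Hilbert envelope and the spike count (half-open
interval convention: a spike exactly at the right edge is excluded).

This module also determines a unit's preferred movement direction (maximal
trial-averaged smoothed rate anywhere after SC onset), applies the 3 Hz
mean-rate inclusion criterion, and equalizes sample counts between the
task-related and trial-by-trial analyses by deterministic halving plus random
reintroduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (DIRECTIONS, EnvelopeTrace, EpochSample, SessionPair,
                   SpikeTrain, TaskTiming, TrialEvents, WindowSample)
from . import signal_processing as sp

WINDOW_MS = 300.0
POST_GO_MS = 1000.0
RATE_THRESHOLD_HZ = 3.0


def cut_windows(events: TrialEvents, envelope: EnvelopeTrace,
                spikes: SpikeTrain, window_ms: float = WINDOW_MS,
                post_go_ms: float = POST_GO_MS) -> List[WindowSample]:
    """Tile [0, t_go + post_go_ms) with consecutive ``window_ms`` windows.

    Windows are aligned to the task timing (trial start), not to movement
    onset.  A final partial window is discarded.
    """
    span = events.t_go + post_go_ms
    n_windows = int(span // window_ms)
    n_need = int(round(n_windows * window_ms * envelope.fs / 1000.0))
    if len(envelope) < n_need:
        raise ValueError("envelope does not cover the analysis span")
    if envelope.t0 != 0:
        raise ValueError("envelope must start at trial start (t0 = 0)")
    out = []
    samples_per_win = int(round(window_ms * envelope.fs / 1000.0))
    for w in range(n_windows):
        t0 = w * window_ms
        t1 = t0 + window_ms
        i0 = w * samples_per_win
        amp = float(envelope.amplitude[i0:i0 + samples_per_win].mean())
        out.append(WindowSample(events.trial_id, w, t0, t1, amp,
                                spikes.count_in(t0, t1)))
    return out


def extract_epoch(events: TrialEvents, envelope: EnvelopeTrace,
                  spikes: SpikeTrain, epoch: str,
                  window_ms: float = WINDOW_MS) -> EpochSample:
    """The 300 ms epoch immediately preceding SC (or TC) onset."""
    if epoch == "pre_SC":
        t_end = events.t_sc_on
    elif epoch == "pre_TC":
        t_end = events.t_tc_on
    else:
        raise ValueError(f"unknown epoch {epoch!r} (expected pre_SC or pre_TC)")
    t_start = t_end - window_ms
    if t_start < 0:
        raise ValueError("epoch starts before trial start")
    i0 = int(round(t_start * envelope.fs / 1000.0))
    i1 = int(round(t_end * envelope.fs / 1000.0))
    if i1 > len(envelope):
        raise ValueError("envelope does not cover the epoch")
    amp = float(envelope.amplitude[i0:i1].mean())
    return EpochSample(events.trial_id, epoch, t_start, t_end, amp,
                       spikes.count_in(t_start, t_end))


def preferred_direction(trials: Sequence[Tuple[TrialEvents, SpikeTrain]],
                        post_go_ms: float = POST_GO_MS,
                        kernel_length_ms: float = 100.0,
                        sigma_ms: float = 50.0) -> Tuple[int, int]:
    """Direction with the maximal trial-averaged smoothed firing rate at any
    time from SC onset to trial end; the nonpreferred direction is the
    opposite one (index + 3 mod 6).

    The PSTH (1 ms bins, Gaussian-smoothed) is computed per direction and
    delay class (event times differ between classes); the score of a
    direction is the global maximum across both classes.  Ties break to the
    lowest direction index.
    """
    if not trials:
        raise ValueError("no trials supplied")
    groups: Dict[Tuple[int, str], list] = {}
    for ev, st in trials:
        groups.setdefault((ev.direction, ev.delay_class), []).append((ev, st))
    best: Dict[int, float] = {}
    for (direction, _), items in groups.items():
        ev0 = items[0][0]
        span = int(round(ev0.t_go + post_go_ms))
        counts = np.zeros(span)
        for ev, st in items:
            t = st.spike_times
            idx = np.floor(t[(t >= 0) & (t < span)]).astype(int)
            np.add.at(counts, idx, 1.0)
        rate = counts / len(items) * 1000.0   # Hz
        rate = sp.gaussian_smooth(rate, kernel_length_ms, sigma_ms)
        post = rate[int(round(ev0.t_sc_on)):]
        if post.size == 0:
            raise ValueError("no data after SC onset")
        score = float(post.max())
        best[direction] = max(best.get(direction, -np.inf), score)
    # lowest index wins ties
    pref = min(sorted(best), key=lambda d: (-best[d], d))
    nonpref = ((pref - 1 + 3) % 6) + 1
    return pref, nonpref


def rate_inclusion(samples: Sequence, threshold_hz: float = RATE_THRESHOLD_HZ,
                   window_ms: float = WINDOW_MS) -> bool:
    """Mean firing rate across windows strictly above ``threshold_hz``."""
    if not samples:
        raise ValueError("no samples supplied")
    counts = np.array([s.spike_count for s in samples], dtype=float)
    return bool(counts.mean() / (window_ms / 1000.0) > threshold_hz)


def _halving_positions(n_total: int, target_n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic part of the subsampling: repeatedly keep every other
    element (positions 0, 2, 4, ... of the current kept list) until no more
    than ``target_n`` remain.  Returns (kept, excluded) original positions."""
    if target_n == 0:
        return np.empty(0, dtype=int), np.arange(n_total)
    kept = np.arange(n_total)
    while kept.size > target_n:
        kept = kept[::2]
    excluded = np.setdiff1d(np.arange(n_total), kept)
    return kept, excluded


def subsample_windows(windows: Sequence, target_n: int,
                      rng: np.random.Generator) -> list:
    """Reduce an ordered window list to exactly ``target_n`` elements.

    Every second window is excluded, repeatedly, until at most ``target_n``
    remain; the selection is then complemented with windows drawn uniformly
    without replacement from the excluded set.  Output preserves the
    original order.
    """
    n = len(windows)
    if target_n > n:
        raise ValueError(f"target_n={target_n} exceeds available windows ({n})")
    if target_n < 0:
        raise ValueError("target_n must be non-negative")
    kept, excluded = _halving_positions(n, target_n)
    need = target_n - kept.size
    if need > 0:
        extra = rng.choice(excluded, size=need, replace=False)
        kept = np.sort(np.concatenate([kept, extra]))
    return [windows[i] for i in kept]


def subsample_positions_batch(n_total: int, target_n: int,
                              rng: np.random.Generator,
                              n_draws: int) -> np.ndarray:
    """Vectorized variant used by the shuffle control: ``n_draws``
    independent subsample index sets, shape (n_draws, target_n), each row
    sorted.  Same scheme as :func:`subsample_windows` (deterministic halving
    shared across draws, random reintroduction per draw)."""
    kept, excluded = _halving_positions(n_total, target_n)
    need = target_n - kept.size
    if need == 0:
        return np.broadcast_to(kept, (n_draws, kept.size)).copy()
    order = np.argsort(rng.random((n_draws, excluded.size)), axis=1)[:, :need]
    extra = excluded[order]
    full = np.concatenate([np.broadcast_to(kept, (n_draws, kept.size)), extra], axis=1)
    full.sort(axis=1)
    return full


# ---------------------------------------------------------------------------
# Prepared pair: everything the correlation/shuffle/locking analyses need,
# computed once per (pair, band).
# ---------------------------------------------------------------------------

@dataclass
class PreparedPair:
    """Windowed and epoched view of one beta-neuron pair for one beta band."""

    pair_id: int
    band_center: float
    band_half_width: float
    events: Dict[int, TrialEvents]                  # by trial_id
    windows: Dict[int, List[WindowSample]]          # by trial_id
    epochs: Dict[Tuple[int, str], EpochSample]      # (trial_id, epoch)
    pref_direction: int
    nonpref_direction: int
    # D1 phase matrices per delay class: (trial_ids, phases[n_trials, d1_len],
    # spike sample indices per trial) -- used for phase locking + its shuffle
    d1_phases: Dict[str, Tuple[List[int], np.ndarray, List[np.ndarray]]] = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def trial_ids(self, direction_class: Optional[str] = None,
                  delay_class: Optional[str] = None) -> List[int]:
        if direction_class in ("preferred", None, "pooled"):
            directions = None if direction_class in (None, "pooled") else {self.pref_direction}
        elif direction_class == "nonpreferred":
            directions = {self.nonpref_direction}
        else:
            raise ValueError(f"unknown direction_class {direction_class!r}")
        out = []
        for tid, ev in self.events.items():
            if directions is not None and ev.direction not in directions:
                continue
            if delay_class is not None and ev.delay_class != delay_class:
                continue
            out.append(tid)
        return sorted(out)

    def window_matrices(self, direction_class: str,
                        delay_class: str) -> Tuple[List[int], np.ndarray, np.ndarray]:
        """(trial_ids, amplitude[n_trials, n_windows], counts[...]) for the
        trials of one direction class and delay class.  Within a delay class
        all trials have the same number of windows."""
        tids = self.trial_ids(direction_class, delay_class)
        if not tids:
            raise ValueError("no trials for this direction/delay subset")
        amp = np.array([[w.mean_beta_amplitude for w in self.windows[t]] for t in tids])
        cnt = np.array([[w.spike_count for w in self.windows[t]] for t in tids], dtype=float)
        return tids, amp, cnt


def prepare_pair(pair: SessionPair, band_center: float,
                 band_half_width: float = 5.0,
                 window_ms: float = WINDOW_MS,
                 post_go_ms: float = POST_GO_MS) -> PreparedPair:
    """Filter, envelope and segment every trial of a pair for one band."""
    events = {ev.trial_id: ev for ev in pair.events}
    windows: Dict[int, List[WindowSample]] = {}
    epochs: Dict[Tuple[int, str], EpochSample] = {}
    d1_store: Dict[str, Tuple[list, list, list]] = {}
    for tid, ev in events.items():
        lfp = pair.lfps[tid]
        st = pair.spikes[tid]
        filt = sp.bandpass_filter(lfp, band_center, band_half_width)
        env = sp.analytic_envelope_phase(filt, band_center, band_half_width)
        windows[tid] = cut_windows(ev, env, st, window_ms, post_go_ms)
        for ep in ("pre_SC", "pre_TC"):
            epochs[(tid, ep)] = extract_epoch(ev, env, st, ep, window_ms)
        # D1 phase snippet [TC offset, SC onset) + this trial's D1 spike indices
        i0 = int(round(ev.t_tc_off))
        i1 = int(round(ev.t_sc_on))
        phases = env.phase[i0:i1]
        t = st.spike_times
        in_d1 = (t >= ev.t_tc_off) & (t < ev.t_sc_on)
        idx = np.floor(t[in_d1] - ev.t_tc_off).astype(int)
        tids_l, ph_l, idx_l = d1_store.setdefault(ev.delay_class, ([], [], []))
        tids_l.append(tid)
        ph_l.append(phases)
        idx_l.append(idx)
    d1_phases = {}
    for dc, (tids_l, ph_l, idx_l) in d1_store.items():
        order = np.argsort(tids_l)
        d1_phases[dc] = ([tids_l[i] for i in order],
                         np.array([ph_l[i] for i in order]),
                         [idx_l[i] for i in order])
    trials = [(ev, pair.spikes[tid]) for tid, ev in events.items()]
    pref, nonpref = preferred_direction(trials, post_go_ms)
    return PreparedPair(pair.pair_id, band_center, band_half_width, events,
                        windows, epochs, pref, nonpref, d1_phases,
                        dict(pair.ground_truth))
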