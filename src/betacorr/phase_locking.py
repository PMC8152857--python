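"""Locking of spike times to the LFP beta phase in delay D1.

Significant spike-to-phase locking of the local population indicates that
the beta oscillation is at least partly locally generated.  Locking is
quantified over the whole first delay D1 = [TC offset, SC onset) of
long-delay trials, accumulated across trials, with the Rayleigh test of
circular nonuniformity (statistic z = n·R², R the mean resultant length).
Only units with more than 50 spikes in D1 are evaluated (strict).
Significance is assessed against a trial-shuffle null — 1000 recombinations
of beta phases and spike times from different trials — rather than from the
parametric Rayleigh p-value, which is reported for reference only.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .core import PhaseLockResult
from .correlation import ALPHA
from .segmentation import PreparedPair
from .shuffle_controls import survival_threshold

MIN_SPIKES = 50


def spike_phases(pair: PreparedPair, delay_class: str = "long") -> np.ndarray:
    """Beta phase at each spike time within D1, accumulated across trials."""
    if delay_class not in pair.d1_phases:
        raise ValueError(f"no {delay_class}-delay trials prepared")
    tids, phases, spike_idx = pair.d1_phases[delay_class]
    out = [phases[i][idx] for i, idx in enumerate(spike_idx)]
    return np.concatenate(out) if out else np.empty(0)


def rayleigh_test(phases: np.ndarray) -> Tuple[float, float, float]:
    """Rayleigh test of circular uniformity: returns (R, z, p).

    R is the mean resultant length, z = n·R² exactly, and p the standard
    small-sample-corrected approximation
    ``exp(-z)·[1 + (2z - z²)/(4n) - (24z - 132z² + 76z³ - 9z⁴)/(288n²)]``
    (clipped to [0, 1]).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise ValueError("empty phase sample")
    R = float(np.abs(np.exp(1j * phases).mean()))
    z = n * R ** 2
    p = np.exp(-z) * (1.0 + (2.0 * z - z ** 2) / (4.0 * n)
                      - (24.0 * z - 132.0 * z ** 2 + 76.0 * z ** 3
                         - 9.0 * z ** 4) / (288.0 * n ** 2))
    return R, float(z), float(np.clip(p, 0.0, 1.0))


def circular_mean(phases: np.ndarray) -> float:
    return float(np.angle(np.exp(1j * np.asarray(phases)).mean()))


def _shuffled_z(pair: PreparedPair, delay_class: str, n_reps: int,
                rng: np.random.Generator) -> np.ndarray:
    """z-statistics of ``n_reps`` trial-shuffled phase samples, vectorized
    via the per-trial-pair resultant table C[a, b] = Σ_k exp(i·φ_a[idx_b,k])
    so each repetition is a single gather-and-sum."""
    tids, phases, spike_idx = pair.d1_phases[delay_class]
    n_trials = len(tids)
    E = np.exp(1j * phases)                        # (n_trials, d1_len)
    C = np.zeros((n_trials, n_trials), dtype=complex)
    for b, idx in enumerate(spike_idx):
        if idx.size:
            C[:, b] = E[:, idx].sum(axis=1)
    n_spikes = sum(idx.size for idx in spike_idx)
    perms = np.argsort(rng.random((n_reps, n_trials)), axis=1)
    cols = np.arange(n_trials)
    resultants = np.abs(C[perms, cols].sum(axis=1)) / n_spikes
    return n_spikes * resultants ** 2


def phase_lock_significance(pair: PreparedPair, n_reps: int = 1000,
                            rng: Optional[np.random.Generator] = None,
                            delay_class: str = "long",
                            alpha: float = ALPHA,
                            min_spikes: int = MIN_SPIKES) -> PhaseLockResult:
    """Shuffle-calibrated phase locking of one unit to one beta band.

    Units with ``min_spikes`` or fewer D1 spikes are returned unevaluated.
    The unit is significant when its observed Rayleigh z exceeds at least
    ceil((1-alpha)·n_reps) of the shuffled z values.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    ph = spike_phases(pair, delay_class)
    n = ph.size
    if n <= min_spikes:
        return PhaseLockResult(pair.pair_id, pair.band_center, n, np.nan,
                               np.nan, np.nan, -1, significant=False,
                               evaluated=False)
    R, z, p = rayleigh_test(ph)
    z_sh = _shuffled_z(pair, delay_class, n_reps, rng)
    eps = 1e-12
    exceed = int(np.sum(z_sh >= z - eps))
    significant = exceed < survival_threshold(n_reps, alpha)
    return PhaseLockResult(pair.pair_id, pair.band_center, n, R, z, p,
                           exceed, significant=significant, evaluated=True)
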