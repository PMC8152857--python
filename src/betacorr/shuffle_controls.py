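"""Trial-shuffling surrogate controls.

A significant task-related correlation can arise from the two signals being
modulated by the task concurrently but independently.  The control destroys
the fine within-trial pairing while preserving global task-locked structure:
the envelope of trial π(i) is paired with the spike counts of trial i (same
window indices, same direction/delay subset), the full analysis — including
a fresh window subsampling — is recomputed, and this is repeated
``n_reps`` (default 1000) times.  A pair "survives" when the observed
correlation is stronger in magnitude than at least 990/1000 shuffled ones
(equivalent to p < 0.01).  Because most observed correlations are negative,
the comparison uses |rho|; the literal signed comparison is also recorded.
"""

from __future__ import annotations

from math import ceil
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import ShuffleOutcome
from .correlation import ALPHA, task_related_correlation
from .segmentation import PreparedPair, subsample_positions_batch, WINDOW_MS


def shuffle_trial_labels(trial_ids: Sequence[int],
                         rng: np.random.Generator) -> np.ndarray:
    """A uniform random permutation of trial ids (fixed points allowed)."""
    ids = np.asarray(trial_ids)
    if ids.size < 2:
        raise ValueError("need at least 2 trials to shuffle")
    return ids[rng.permutation(ids.size)]


def survival_threshold(n_reps: int, alpha: float = ALPHA) -> int:
    """Largest exceed count that still counts as surviving: the observed
    statistic must beat at least ceil((1-alpha)·n_reps) shuffles."""
    return n_reps - ceil((1.0 - alpha) * n_reps) + 1


def _rowwise_spearman(amp: np.ndarray, cnt: np.ndarray) -> np.ndarray:
    """Spearman rho per row of two (n_reps, n) matrices (ties -> average
    ranks).  Undefined rows (constant input) come out as 0."""
    ra = stats.rankdata(amp, method="average", axis=1)
    rc = stats.rankdata(cnt, method="average", axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rc = rc - rc.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra ** 2).sum(axis=1) * (rc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra * rc).sum(axis=1) / denom
    return np.where(np.isfinite(rho), rho, 0.0)


def trial_shuffle_correlation(pair: PreparedPair, direction_class: str,
                              delay_class: str, n_reps: int = 1000,
                              rng: Optional[np.random.Generator] = None,
                              alpha: float = ALPHA,
                              rho_observed: Optional[float] = None
                              ) -> ShuffleOutcome:
    """The 1000-fold trial-shuffle control of the task-related correlation.

    When ``rho_observed`` is omitted it is recomputed here with the same
    rng (callers normally pass the already-computed observed rho so the
    shuffle distribution is conditionally independent of it).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    if rho_observed is None:
        res = task_related_correlation(pair, direction_class, delay_class, rng, alpha)
        if res.excluded or not res.defined:
            raise ValueError(f"observed correlation unavailable: {res.exclusion_reason}")
        rho_observed = res.rho
    tids, amp, cnt = pair.window_matrices(direction_class, delay_class)
    n_trials, n_windows = amp.shape
    if n_trials < 2:
        raise ValueError("need at least 2 trials to shuffle")
    n_target = len(pair.trial_ids(None, delay_class))
    n_total = n_trials * n_windows
    if n_target > n_total:
        raise ValueError("fewer windows than required sample count")
    perms = np.argsort(rng.random((n_reps, n_trials)), axis=1)
    amp_shuf = amp[perms].reshape(n_reps, n_total)       # envelope re-paired
    cnt_flat = np.broadcast_to(cnt.ravel(), (n_reps, n_total))
    sel = subsample_positions_batch(n_total, n_target, rng, n_reps)
    rows = np.arange(n_reps)[:, None]
    rhos = _rowwise_spearman(amp_shuf[rows, sel], cnt_flat[rows, sel])
    eps = 1e-12
    exceed = int(np.sum(np.abs(rhos) >= abs(rho_observed) - eps))
    thresh = survival_threshold(n_reps, alpha)
    signed_exceed = int(np.sum(rhos >= rho_observed - eps))
    return ShuffleOutcome(pair.pair_id, float(rho_observed), rhos, exceed,
                          survives=exceed < thresh, n_reps=n_reps,
                          signed_exceed_count=signed_exceed,
                          signed_survives=signed_exceed < thresh)


def shuffle_phase_pairing(pair: PreparedPair, rng: np.random.Generator,
                          delay_class: str = "long"
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """One shuffled spike/phase assignment for the phase-locking control.

    Spike times of trial i read beta phases from trial π(i) at identical
    within-D1 times.  Trial durations are matched within a delay class, so
    the permutation is always valid there.  Returns (permutation, phases).
    """
    if delay_class not in pair.d1_phases:
        raise ValueError(f"no {delay_class}-delay trials prepared")
    tids, phases, spike_idx = pair.d1_phases[delay_class]
    n_trials = len(tids)
    if sum(idx.size > 0 for idx in spike_idx) < 2:
        raise ValueError("need at least 2 trials with spikes in D1")
    perm = rng.permutation(n_trials)
    out = [phases[perm[i]][spike_idx[i]] for i in range(n_trials)]
    return perm, np.concatenate(out) if out else np.empty(0)
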