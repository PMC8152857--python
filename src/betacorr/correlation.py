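"""Rank correlations between beta amplitude and spike count.

Two complementary analyses:

* **Task-related** — 300 ms windows pooled across all trial epochs of one
  movement direction and delay class, subsampled to as many windows as the
  pair has trials of that delay class (so both analyses have comparable
  statistical power), then Spearman-correlated.  Because both signals are
  systematically modulated by the task, these correlations can be driven by
  shared task structure alone.
* **Trial-by-trial** — one fixed pre-SC (or pre-TC) epoch per trial,
  correlated across trials with all directions pooled, one delay class at a
  time.  This isolates intrinsic covariation.

Spearman's rho is the Pearson correlation of average ranks.  The two-sided
p-value is computed by exact permutation enumeration for n ≤ 8, seeded
Monte-Carlo permutation (10^4 draws) for n ≤ 20, and the t-approximation
above that.  Correlations with p < 0.01 are considered significant.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import CorrelationResult, VariabilitySummary, fisher_z
from .segmentation import (PreparedPair, rate_inclusion, subsample_windows,
                           RATE_THRESHOLD_HZ, WINDOW_MS)

ALPHA = 0.01
EXACT_N_MAX = 8
MC_N_MAX = 20
N_MC = 10_000


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two (already ranked) vectors."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman_rho(x: Sequence[float], y: Sequence[float],
                 rng: Optional[np.random.Generator] = None,
                 ) -> Tuple[float, float]:
    """Spearman's rho with a sample-size-adaptive two-sided p-value.

    Returns ``(nan, nan)`` when either input is constant (the correlation
    is undefined; callers flag and exclude such samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rx, ry = _rank(x), _rank(y)
    rho = rho_of_ranks(rx, ry)
    eps = 1e-12
    if n <= EXACT_N_MAX:
        count = 0
        for perm in permutations(range(n)):
            if abs(rho_of_ranks(rx, ry[list(perm)])) >= abs(rho) - eps:
                count += 1
        p = count / factorial(n)
    elif n <= MC_N_MAX:
        if rng is None:
            rng = np.random.default_rng(0)
        perms = np.argsort(rng.random((N_MC, n)), axis=1)
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        rhos = (ry_c[perms] * rx_c).sum(axis=1) / denom
        p = (1 + int(np.sum(np.abs(rhos) >= abs(rho) - eps))) / (N_MC + 1)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def _result(pair_id: int, analysis: str, direction_class: str,
            delay_class: str, band: float, n: int, rho: float, p: float,
            alpha: float) -> CorrelationResult:
    defined = np.isfinite(rho)
    significant = bool(defined and p < alpha)
    return CorrelationResult(pair_id, analysis, direction_class, delay_class,
                             n, rho, p, significant,
                             fisher_z(rho) if defined else np.nan,
                             band_center=band, defined=defined)


def _excluded(pair_id: int, analysis: str, direction_class: str,
              delay_class: str, band: float, reason: str) -> CorrelationResult:
    return CorrelationResult(pair_id, analysis, direction_class, delay_class,
                             0, np.nan, np.nan, False, np.nan,
                             band_center=band, defined=False, excluded=True,
                             exclusion_reason=reason)


def task_related_correlation(pair: PreparedPair, direction_class: str,
                             delay_class: str, rng: np.random.Generator,
                             alpha: float = ALPHA,
                             rate_threshold_hz: float = RATE_THRESHOLD_HZ
                             ) -> CorrelationResult:
    """Windowed correlation for one direction class and delay class.

    Pools the 300 ms windows of all trials of the (non)preferred direction,
    checks the 3 Hz inclusion criterion across those windows, subsamples to
    the pair's number of trials of that delay class, and correlates mean
    envelope amplitude against spike count.
    """
    analysis = "task_related"
    band = pair.band_center
    try:
        _, amp, cnt = pair.window_matrices(direction_class, delay_class)
    except ValueError as e:
        return _excluded(pair.pair_id, analysis, direction_class, delay_class,
                         band, str(e))
    counts_flat = cnt.ravel()
    amp_flat = amp.ravel()
    mean_rate = counts_flat.mean() / (WINDOW_MS / 1000.0)
    if not mean_rate > rate_threshold_hz:
        return _excluded(pair.pair_id, analysis, direction_class, delay_class,
                         band, f"mean rate {mean_rate:.2f} Hz not above threshold")
    n_target = len(pair.trial_ids(None, delay_class))
    if n_target > amp_flat.size:
        return _excluded(pair.pair_id, analysis, direction_class, delay_class,
                         band, "fewer windows than target sample count")
    sel = subsample_windows(list(range(amp_flat.size)), n_target, rng)
    sel = np.asarray(sel, dtype=int)
    rho, p = spearman_rho(amp_flat[sel], counts_flat[sel], rng)
    if not np.isfinite(rho):
        return _excluded(pair.pair_id, analysis, direction_class, delay_class,
                         band, "correlation undefined (constant input)")
    return _result(pair.pair_id, analysis, direction_class, delay_class,
                   band, n_target, rho, p, alpha)


def trial_by_trial_correlation(pair: PreparedPair, epoch: str,
                               delay_class: str,
                               rng: Optional[np.random.Generator] = None,
                               alpha: float = ALPHA,
                               rate_threshold_hz: float = RATE_THRESHOLD_HZ,
                               min_trials: int = 8) -> CorrelationResult:
    """Across-trial correlation in one fixed pre-event epoch.

    The movement direction is unknown to the subject in both epochs, so all
    directions are pooled; short and long delay trials are kept separate.
    """
    analysis = "trial_by_trial_preSC" if epoch == "pre_SC" else "trial_by_trial_preTC"
    band = pair.band_center
    tids = pair.trial_ids(None, delay_class)
    if len(tids) < min_trials:
        return _excluded(pair.pair_id, analysis, "pooled", delay_class, band,
                         f"only {len(tids)} trials (< {min_trials})")
    samples = [pair.epochs[(t, epoch)] for t in tids]
    if not rate_inclusion(samples, rate_threshold_hz):
        return _excluded(pair.pair_id, analysis, "pooled", delay_class, band,
                         "mean epoch rate not above threshold")
    amp = np.array([s.mean_beta_amplitude for s in samples])
    cnt = np.array([s.spike_count for s in samples], dtype=float)
    rho, p = spearman_rho(amp, cnt, rng)
    if not np.isfinite(rho):
        return _excluded(pair.pair_id, analysis, "pooled", delay_class, band,
                         "correlation undefined (constant input)")
    return _result(pair.pair_id, analysis, "pooled", delay_class, band,
                   len(tids), rho, p, alpha)


def population_shift_test(results: Iterable[CorrelationResult]) -> float:
    """Two-sided Wilcoxon signed-rank test of the Fisher-z-transformed rho
    values against zero (is the population distribution shifted off zero?)."""
    zs = np.array([r.fisher_z for r in results
                   if r.defined and np.isfinite(r.fisher_z)])
    if zs.size < 10:
        raise ValueError("need at least 10 defined correlations")
    if np.all(zs == 0):
        return 1.0
    return float(stats.wilcoxon(zs, alternative="two-sided").pvalue)


def variability_summary(samples: Sequence, pair_id: int, context: str,
                        delay_class: str) -> VariabilitySummary:
    """Coefficient of variation (SD / mean) of spike count and of beta
    amplitude across the samples entering one correlation."""
    cnt = np.array([s.spike_count for s in samples], dtype=float)
    amp = np.array([s.mean_beta_amplitude for s in samples], dtype=float)

    def cv(v: np.ndarray) -> float:
        m = v.mean()
        return float(v.std(ddof=1) / m) if m > 0 else np.nan

    cv_c, cv_a = cv(cnt), cv(amp)
    return VariabilitySummary(pair_id, cv_c, cv_a, context, delay_class,
                              defined=np.isfinite(cv_c) and np.isfinite(cv_a))


def cv_association(summaries: Sequence[VariabilitySummary],
                   results: Sequence[CorrelationResult],
                   rng: Optional[np.random.Generator] = None) -> dict:
    """Relate per-pair signal variability to correlation strength.

    Spearman-correlates each signal's CV with the pairs' rho values (matched
    by pair id) and, when both contexts are present among the summaries,
    compares CV magnitude between the task-related and pre-SC contexts with
    two-sample t-tests.
    """
    by_pair = {r.pair_id: r for r in results if r.defined and not r.excluded}
    matched = [s for s in summaries if s.defined and s.pair_id in by_pair]
    if len(matched) < 10:
        raise ValueError("need at least 10 matched pairs")
    rhos = np.array([by_pair[s.pair_id].rho for s in matched])
    out = {}
    for name, key in (("spike_count", "cv_spike_count"),
                      ("beta_amplitude", "cv_beta_amplitude")):
        cvs = np.array([getattr(s, key) for s in matched])
        if np.all(cvs == cvs[0]):
            out[name] = (np.nan, np.nan)
        else:
            out[name] = spearman_rho(cvs, rhos, rng)
    ctx = {c: [s for s in summaries if s.defined and s.context == c]
           for c in ("task_related", "pre_SC")}
    if all(len(v) >= 2 for v in ctx.values()):
        comp = {}
        for name, key in (("spike_count", "cv_spike_count"),
                          ("beta_amplitude", "cv_beta_amplitude")):
            a = np.array([getattr(s, key) for s in ctx["task_related"]])
            b = np.array([getattr(s, key) for s in ctx["pre_SC"]])
            t, p = stats.ttest_ind(a, b)
            comp[name] = {"t": float(t), "p": float(p),
                          "mean_task_related": float(a.mean()),
                          "mean_pre_SC": float(b.mean())}
        out["context_comparison"] = comp
    return out
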