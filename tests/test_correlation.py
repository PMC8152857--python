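"""Spearman machinery, population shift test, CV association."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from betacorr.core import CorrelationResult, VariabilitySummary, fisher_z
from betacorr.correlation import (cv_association, population_shift_test,
                                  rho_of_ranks, spearman_rho,
                                  task_related_correlation,
                                  trial_by_trial_correlation,
                                  variability_summary)


def test_perfect_monotone_association(rng):
    x = np.arange(10.0)
    rho, p = spearman_rho(x, x ** 3, rng)
    assert rho == pytest.approx(1.0)
    assert p < 0.01
    rho_neg, _ = spearman_rho(x, -x, rng)
    assert rho_neg == pytest.approx(-1.0)


def test_tied_ranks_match_hand_computed_oracle():
    """x=[1,2,2,3], y=[2,1,3,3]: rho is the Pearson correlation of the
    average ranks [1, 2.5, 2.5, 4] and [2, 1, 3.5, 3.5]."""
    rx = stats.rankdata([1, 2, 2, 3])
    ry = stats.rankdata([2, 1, 3, 3])
    np.testing.assert_array_equal(rx, [1, 2.5, 2.5, 4])
    np.testing.assert_array_equal(ry, [2, 1, 3.5, 3.5])
    expected = np.corrcoef(rx, ry)[0, 1]
    assert rho_of_ranks(rx, ry) == pytest.approx(expected, abs=1e-12)


def test_exact_permutation_p_equals_brute_force(rng):
    """For n <= 8 the p-value enumerates all n! pairings; compare with an
    independent brute-force permutation test."""
    for seed in (0, 1, 2):
        r = np.random.default_rng(seed)
        x = r.normal(size=7)
        y = 0.7 * x + r.normal(size=7)
        rho, p = spearman_rho(x, y)

        def statistic(yy):
            return stats.spearmanr(x, yy).statistic

        ref = stats.permutation_test(
            (y,), statistic, permutation_type="pairings",
            alternative="two-sided", n_resamples=np.inf)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_input_validation_and_degenerate_cases(rng):
    with pytest.raises(ValueError):
        spearman_rho([1, 2, 3], [1, 2], rng)
    with pytest.raises(ValueError):
        spearman_rho([1, 2, 3, 4], [1, 2, 3, 4], rng)
    rho, p = spearman_rho(np.ones(10), np.arange(10.0), rng)
    assert np.isnan(rho) and np.isnan(p)


@given(st.integers(min_value=0, max_value=10_000))
def test_invariance_under_monotone_transform(seed):
    r = np.random.default_rng(seed)
    x = r.normal(size=12)
    y = r.normal(size=12)
    rng1 = np.random.default_rng(99)
    rng2 = np.random.default_rng(99)
    rho1, p1 = spearman_rho(x, y, rng1)
    rho2, p2 = spearman_rho(np.exp(x), y, rng2)
    assert rho1 == pytest.approx(rho2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_type_one_error_calibration_large_n():
    """Under independence (bivariate normal, rho = 0) the t-approximation
    path rejects at alpha = 0.01 with the nominal rate."""
    r = np.random.default_rng(2024)
    n_rep, n = 10_000, 30
    x = r.normal(size=(n_rep, n))
    y = r.normal(size=(n_rep, n))
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    rho = (rx * ry).sum(axis=1) / np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    # spot-check the vectorized replicate against the implementation
    rho0, p0 = spearman_rho(x[0], y[0])
    assert rho0 == pytest.approx(rho[0], abs=1e-12)
    assert p0 == pytest.approx(p[0], abs=1e-12)
    rate = np.mean(p < 0.01)
    assert 0.005 <= rate <= 0.02


def test_population_shift_test_behavior():
    sym = [_res(i, rho) for i, rho in enumerate([0.2] * 25 + [-0.2] * 25)]
    assert population_shift_test(sym) > 0.05
    shifted = [_res(i, -0.3) for i in range(50)]
    assert population_shift_test(shifted) < 1e-8
    with pytest.raises(ValueError):
        population_shift_test([])


def test_fisher_z_clipped_at_perfect_correlation():
    assert np.isfinite(fisher_z(1.0))
    assert np.isfinite(fisher_z(-1.0))
    assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))


def _res(pair_id, rho, analysis="task_related"):
    return CorrelationResult(pair_id, analysis, "preferred", "short", 40,
                             rho, 0.5, False, fisher_z(rho), 22.0)


def test_cv_association_null_calibration():
    """When CV is independent of rho by construction, the association test
    rejects at alpha = 0.01 about 1% of the time."""
    r = np.random.default_rng(7)
    n_rep, n_pairs = 500, 30
    n_sig = 0
    for _ in range(n_rep):
        summaries = [VariabilitySummary(i, r.random() + 0.5, r.random() + 0.5,
                                        "task_related") for i in range(n_pairs)]
        results = [_res(i, np.tanh(r.normal(scale=0.3))) for i in range(n_pairs)]
        out = cv_association(summaries, results)
        n_sig += out["spike_count"][1] < 0.01
    lo, hi = stats.binom.ppf([0.005, 0.995], n_rep, 0.01)
    assert lo <= n_sig <= hi


def test_cv_association_constant_cv_flagged():
    summaries = [VariabilitySummary(i, 1.0, 1.0, "task_related")
                 for i in range(20)]
    results = [_res(i, 0.1 * (i - 10) / 10) for i in range(20)]
    out = cv_association(summaries, results)
    assert np.isnan(out["spike_count"][0])
    assert np.isnan(out["beta_amplitude"][0])


def test_pre_sc_envelope_less_variable_than_task_windows(small_prepared):
    """Across-trial envelope CV in the fixed pre-SC epoch is smaller than
    the across-window CV of the task-related analysis, which spans epochs
    with very different beta levels."""
    prepared = small_prepared
    tids = prepared.trial_ids("preferred", "short")
    wins = [w for t in tids for w in prepared.windows[t]]
    task = variability_summary(wins, 0, "task_related", "short")
    eps = [prepared.epochs[(t, "pre_SC")]
           for t in prepared.trial_ids(None, "short")]
    pre = variability_summary(eps, 0, "pre_SC", "short")
    assert pre.cv_beta_amplitude < task.cv_beta_amplitude


def test_task_related_exclusions(small_prepared, rng):
    """A silent unit fails the 3 Hz criterion and is excluded with a
    reason, not silently dropped."""
    import copy
    prepared = copy.deepcopy(small_prepared)
    from betacorr.core import WindowSample
    for tid in prepared.windows:
        prepared.windows[tid] = [
            WindowSample(w.trial_id, w.window_index, w.t_start, w.t_end,
                         w.mean_beta_amplitude, 0)
            for w in prepared.windows[tid]]
    res = task_related_correlation(prepared, "preferred", "short", rng)
    assert res.excluded
    assert "rate" in res.exclusion_reason


def test_trial_by_trial_min_trials(small_prepared, rng):
    res = trial_by_trial_correlation(small_prepared, "pre_SC", "short", rng,
                                     min_trials=999)
    assert res.excluded
    assert "trials" in res.exclusion_reason
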