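"""End-to-end orchestration: simulate → process → analyze → report.

``run_analysis`` executes, per beta-neuron pair and band: band-pass
filtering → Hilbert envelope → windowing/epoching → inclusion criteria →
preferred direction → task-related correlations (preferred and nonpreferred
direction, short and long delays) → trial-shuffle controls → trial-by-trial
correlations (pre-SC and pre-TC) → CV analyses → phase locking.  The report
table mirrors the shape of the study's summary table: per (band, analysis,
direction class, delay class) the number of analyzed pairs, significant
pairs, negative-significant pairs, shuffle survivors, and the population
shift-test p-value.

Randomness is organized as named substreams of one master seed, keyed by
(pair, band, analysis), so adding pairs or toggling analyses never perturbs
existing results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (CorrelationResult, PhaseLockResult, Session,
                   ShuffleOutcome, VariabilitySummary)
from . import correlation as corr
from . import phase_locking as pl
from . import shuffle_controls as shuf
from .segmentation import PreparedPair, prepare_pair

# substream codes per analysis family
_CODES = {"task_related": 1, "shuffle": 2, "trial_by_trial": 3,
          "phase_locking": 4, "cv": 5}


@dataclass
class PipelineConfig:
    """Fixed constants of the analysis, with the study's defaults."""

    bands: Tuple[Tuple[float, float], ...] = ((22.0, 5.0),)
    alpha: float = 0.01
    n_shuffle_reps: int = 1000
    window_ms: float = 300.0
    post_go_ms: float = 1000.0
    rate_threshold_hz: float = 3.0
    min_trials: int = 8
    master_seed: int = 0
    run_task_related: bool = True
    run_trial_by_trial: bool = True
    run_shuffle: bool = True
    shuffle_all_pairs: bool = False   # default: shuffle only significant pairs
    run_phase_locking: bool = True
    run_cv: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.window_ms <= 0 or self.rate_threshold_hz <= 0 or self.min_trials <= 0:
            raise ValueError("window, rate threshold and min_trials must be positive")


@dataclass
class AnalysisResults:
    correlations: List[CorrelationResult] = field(default_factory=list)
    shuffles: Dict[tuple, ShuffleOutcome] = field(default_factory=dict)
    phase_locks: List[PhaseLockResult] = field(default_factory=list)
    variability: List[VariabilitySummary] = field(default_factory=list)
    cv_associations: dict = field(default_factory=dict)
    exclusions: List[dict] = field(default_factory=list)
    report: Optional[pd.DataFrame] = None


def _rng(master_seed: int, pair_id: int, band_index: int, code: int,
         extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([master_seed, pair_id, band_index, code, extra])


def _analyze_prepared(prepared: PreparedPair, band_index: int,
                      config: PipelineConfig, results: AnalysisResults) -> None:
    pid = prepared.pair_id
    a = config.alpha
    if config.run_task_related:
        for direction_class in ("preferred", "nonpreferred"):
            for k, delay_class in enumerate(("short", "long")):
                rng = _rng(config.master_seed, pid, band_index,
                           _CODES["task_related"],
                           extra=2 * k + (direction_class == "nonpreferred"))
                res = corr.task_related_correlation(
                    prepared, direction_class, delay_class, rng, a,
                    config.rate_threshold_hz)
                results.correlations.append(res)
                if res.excluded:
                    results.exclusions.append(_exclusion_row(prepared, res))
                    continue
                if config.run_shuffle and (res.significant or config.shuffle_all_pairs):
                    rng_s = _rng(config.master_seed, pid, band_index,
                                 _CODES["shuffle"],
                                 extra=2 * k + (direction_class == "nonpreferred"))
                    outcome = shuf.trial_shuffle_correlation(
                        prepared, direction_class, delay_class,
                        config.n_shuffle_reps, rng_s, a, rho_observed=res.rho)
                    results.shuffles[(pid, prepared.band_center,
                                      direction_class, delay_class)] = outcome
    if config.run_trial_by_trial:
        for e, epoch in enumerate(("pre_SC", "pre_TC")):
            for k, delay_class in enumerate(("short", "long")):
                rng = _rng(config.master_seed, pid, band_index,
                           _CODES["trial_by_trial"], extra=2 * k + e)
                res = corr.trial_by_trial_correlation(
                    prepared, epoch, delay_class, rng, a,
                    config.rate_threshold_hz, config.min_trials)
                results.correlations.append(res)
                if res.excluded:
                    results.exclusions.append(_exclusion_row(prepared, res))
    if config.run_cv:
        for delay_class in ("short", "long"):
            tids_pref = prepared.trial_ids("preferred", delay_class)
            if tids_pref:
                wins = [w for t in tids_pref for w in prepared.windows[t]]
                results.variability.append(corr.variability_summary(
                    wins, pid, "task_related", delay_class))
            tids_all = prepared.trial_ids(None, delay_class)
            if tids_all:
                eps = [prepared.epochs[(t, "pre_SC")] for t in tids_all]
                results.variability.append(corr.variability_summary(
                    eps, pid, "pre_SC", delay_class))
    if config.run_phase_locking and "long" in prepared.d1_phases:
        rng = _rng(config.master_seed, pid, band_index, _CODES["phase_locking"])
        results.phase_locks.append(pl.phase_lock_significance(
            prepared, config.n_shuffle_reps, rng, "long", a))


def _exclusion_row(prepared: PreparedPair, res: CorrelationResult) -> dict:
    return {"pair_id": res.pair_id, "band": prepared.band_center,
            "analysis": res.analysis, "direction_class": res.direction_class,
            "delay_class": res.delay_class, "reason": res.exclusion_reason}


def _build_report(results: AnalysisResults, alpha: float) -> pd.DataFrame:
    rows = []
    keys = sorted({(r.band_center, r.analysis, r.direction_class, r.delay_class)
                   for r in results.correlations})
    for band, analysis, direction_class, delay_class in keys:
        group = [r for r in results.correlations
                 if (r.band_center, r.analysis, r.direction_class,
                     r.delay_class) == (band, analysis, direction_class, delay_class)]
        analyzed = [r for r in group if not r.excluded]
        sig = [r for r in analyzed if r.significant]
        neg = [r for r in sig if r.rho < 0]
        surv = sum(1 for r in sig
                   if results.shuffles.get((r.pair_id, band, direction_class,
                                            delay_class), None) is not None
                   and results.shuffles[(r.pair_id, band, direction_class,
                                         delay_class)].survives)
        try:
            shift_p = corr.population_shift_test(analyzed)
        except ValueError:
            shift_p = np.nan
        rows.append({
            "band": band, "analysis": analysis,
            "direction_class": direction_class, "delay_class": delay_class,
            "n_pairs_analyzed": len(analyzed), "n_excluded": len(group) - len(analyzed),
            "n_significant": len(sig),
            "fraction_significant": len(sig) / len(analyzed) if analyzed else np.nan,
            "n_negative_of_significant": len(neg),
            "n_surviving_shuffle": surv,
            "population_shift_p": shift_p,
        })
    return pd.DataFrame(rows)


def run_analysis(session: Session, config: PipelineConfig,
                 out_dir: Optional[Path] = None) -> AnalysisResults:
    """Run the full analysis on a session; optionally write report files."""
    results = AnalysisResults()
    for band_index, (center, half_width) in enumerate(config.bands):
        for pair in session.pairs:
            prepared = prepare_pair(pair, center, half_width,
                                    config.window_ms, config.post_go_ms)
            _analyze_prepared(prepared, band_index, config, results)
    if config.run_cv:
        try:
            task_res = [r for r in results.correlations
                        if r.analysis == "task_related"
                        and r.direction_class == "preferred"
                        and r.delay_class == "short" and not r.excluded]
            summaries = [s for s in results.variability if s.delay_class == "short"]
            rng = _rng(config.master_seed, 0, 0, _CODES["cv"])
            results.cv_associations = corr.cv_association(summaries, task_res, rng)
        except ValueError:
            results.cv_associations = {}
    results.report = _build_report(results, config.alpha)
    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def summarize_distributions(results: Sequence[CorrelationResult],
                            bin_width: float = 0.05) -> dict:
    """Population summary of one analysis row: median rho, Fisher-z shift
    test p, and a fixed-width histogram over [-1, 1]."""
    defined = [r for r in results if r.defined and not r.excluded]
    if len(defined) < 10:
        raise ValueError("need at least 10 defined correlations")
    rhos = np.array([r.rho for r in defined])
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(rhos, bins=edges)
    return {"n": rhos.size, "median_rho": float(np.median(rhos)),
            "shift_p": corr.population_shift_test(defined),
            "hist_edges": edges.tolist(), "hist_counts": counts.tolist()}


def _write_outputs(results: AnalysisResults, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    results.report.to_csv(out_dir / "report.csv", index=False)
    payload = {"report": results.report.to_dict(orient="records"),
               "cv_associations": _jsonable(results.cv_associations),
               "n_exclusions": len(results.exclusions)}
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
    pairs_dir = out_dir / "pairs"
    pairs_dir.mkdir(exist_ok=True)
    df = pd.DataFrame([dataclasses.asdict(r) for r in results.correlations])
    for pid, sub in df.groupby("pair_id"):
        sub.to_csv(pairs_dir / f"pair_{pid:04d}.csv", index=False)
    if results.exclusions:
        pd.DataFrame(results.exclusions).to_csv(out_dir / "exclusions.csv",
                                                index=False)
    if results.phase_locks:
        pd.DataFrame([dataclasses.asdict(r) for r in results.phase_locks]
                     ).to_csv(out_dir / "phase_locking.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
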