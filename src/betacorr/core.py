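"""Core data containers for task-structured electrophysiology sessions.

The experiment emulated here is a delayed center-out reaching task: the
subject initiates a trial by holding a central target, receives an auditory
temporal cue (TC) announcing the delay duration, waits through a first delay
(D1), sees a brief visual spatial cue (SC) indicating one of six movement
directions, waits through a second delay (D2) of the same duration, and moves
at the GO signal.  Local field potentials (LFPs) are stored at 1 kHz together
with sorted single-unit spike times.

Everything downstream (filtering, windowing, correlation, shuffling, phase
locking) operates on the small value types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

DIRECTIONS = (1, 2, 3, 4, 5, 6)
DELAY_CLASSES = ("short", "long")

#: Trial epochs in temporal order.  ``sc`` is the brief spatial-cue flash,
#: ``post_go`` the reaction-time period between GO and movement onset.
EPOCHS = ("pre_tc", "tc", "d1", "sc", "d2", "post_go", "move")


@dataclass(frozen=True)
class TaskTiming:
    """Fixed epoch durations of the behavioral task, in milliseconds.

    Defaults are the monkey-T-like parameterization; use :meth:`monkey_m`
    for the monkey-M-like one (longer delays, slower reactions).  Within a
    delay class the two delays D1 and D2 share the same duration.
    """

    start_to_tc: float = 700.0
    tc_dur: float = 200.0
    d1_short: float = 700.0
    d1_long: float = 1500.0
    sc_dur: float = 55.0
    d2_short: float = 700.0
    d2_long: float = 1500.0
    post_go_analysis: float = 1000.0
    rt_mean: float = 160.0
    rt_sd: float = 35.0
    mt_mean: float = 300.0
    mt_sd: float = 20.0

    def __post_init__(self) -> None:
        for name in ("start_to_tc", "tc_dur", "d1_short", "d1_long", "sc_dur",
                     "d2_short", "d2_long", "post_go_analysis"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TaskTiming.{name} must be > 0")
        if self.d1_short != self.d2_short or self.d1_long != self.d2_long:
            raise ValueError("D1 and D2 must have equal duration within a delay class")

    @classmethod
    def monkey_t(cls) -> "TaskTiming":
        return cls()

    @classmethod
    def monkey_m(cls) -> "TaskTiming":
        return cls(d1_short=1000.0, d1_long=2000.0, d2_short=1000.0,
                   d2_long=2000.0, rt_mean=230.0, rt_sd=45.0,
                   mt_mean=300.0, mt_sd=26.0)

    def delay(self, delay_class: str) -> float:
        if delay_class not in DELAY_CLASSES:
            raise ValueError(f"unknown delay class {delay_class!r}")
        return self.d1_short if delay_class == "short" else self.d1_long

    def go_time(self, delay_class: str) -> float:
        d = self.delay(delay_class)
        return self.start_to_tc + self.tc_dur + d + self.sc_dur + d

    def analysis_span(self, delay_class: str) -> float:
        """Length of the analyzed trial span [start, GO + post-GO window)."""
        return self.go_time(delay_class) + self.post_go_analysis


@dataclass(frozen=True)
class TrialEvents:
    """Event times of one correct trial, in ms from trial start."""

    trial_id: int
    direction: int
    delay_class: str
    t_start: float
    t_tc_on: float
    t_tc_off: float
    t_sc_on: float
    t_sc_off: float
    t_go: float
    t_move_on: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be in 1..6, got {self.direction}")
        if self.delay_class not in DELAY_CLASSES:
            raise ValueError(f"delay_class must be short|long, got {self.delay_class!r}")
        seq = (self.t_start, self.t_tc_on, self.t_tc_off, self.t_sc_on,
               self.t_sc_off, self.t_go, self.t_move_on)
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("event times must be strictly increasing")

    def epoch_edges(self, span: float) -> np.ndarray:
        """Epoch boundary times (len(EPOCHS)+1 values) over [0, span]."""
        return np.array([0.0, self.t_tc_on, self.t_tc_off, self.t_sc_on,
                         self.t_sc_off, self.t_go, self.t_move_on, span])

    def epoch_of(self, t: np.ndarray, span: float) -> np.ndarray:
        """Epoch index (into EPOCHS) for each time in ``t`` (ms); times
        before trial start map to ``pre_tc``."""
        edges = self.epoch_edges(span)
        idx = np.searchsorted(edges[1:-1], np.asarray(t, dtype=float), side="right")
        return idx


@dataclass
class AnalogTrace:
    """A continuous signal (LFP or derived), uniformly sampled."""

    samples: np.ndarray
    fs: float = 1000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class EnvelopeTrace:
    """Instantaneous amplitude and phase of a band-passed signal.

    ``amplitude`` is the modulus and ``phase`` the argument of the analytic
    signal (Hilbert transform); phase is 0 at local maxima of the band-passed
    signal.  ``phase_defined`` is False for degenerate (all-zero) input.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    fs: float
    t0: float
    band_center: float
    band_half_width: float
    phase_defined: bool = True

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must have equal length")
        if np.any(self.amplitude < 0):
            raise ValueError("envelope amplitude must be non-negative")

    def __len__(self) -> int:
        return self.amplitude.size


@dataclass
class SpikeTrain:
    """Spike times of one unit in one trial, ms from trial start, sorted."""

    trial_id: int
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted ascending")

    def __len__(self) -> int:
        return self.spike_times.size

    def count_in(self, t_start: float, t_end: float) -> int:
        """Spike count in the half-open interval [t_start, t_end)."""
        lo, hi = np.searchsorted(self.spike_times, [t_start, t_end], side="left")
        return int(hi - lo)


@dataclass(frozen=True)
class WindowSample:
    """One 300 ms analysis window: mean beta amplitude and spike count."""

    trial_id: int
    window_index: int
    t_start: float
    t_end: float
    mean_beta_amplitude: float
    spike_count: int


@dataclass(frozen=True)
class EpochSample:
    """One fixed pre-event epoch (pre-SC or pre-TC) of one trial."""

    trial_id: int
    epoch: str
    t_start: float
    t_end: float
    mean_beta_amplitude: float
    spike_count: int


@dataclass
class CorrelationResult:
    """Spearman correlation between beta amplitude and spike count."""

    pair_id: int
    analysis: str                 # task_related | trial_by_trial_preSC | trial_by_trial_preTC
    direction_class: str          # preferred | nonpreferred | pooled
    delay_class: str
    n: int
    rho: float
    p: float
    significant: bool
    fisher_z: float
    band_center: float = np.nan
    defined: bool = True
    excluded: bool = False
    exclusion_reason: Optional[str] = None


@dataclass
class VariabilitySummary:
    """Coefficient of variation of the two signals entering a correlation."""

    pair_id: int
    cv_spike_count: float
    cv_beta_amplitude: float
    context: str                  # task_related | pre_SC
    delay_class: str = "short"
    defined: bool = True


@dataclass
class ShuffleOutcome:
    """Result of the 1000-fold trial-shuffling control for one pair."""

    pair_id: int
    rho_observed: float
    shuffled_rhos: np.ndarray
    exceed_count: int
    survives: bool
    n_reps: int = 1000
    signed_exceed_count: int = -1   # literal signed variant, kept for audit
    signed_survives: bool = False


@dataclass
class PhaseLockResult:
    """Spike-to-beta-phase locking of one unit in delay D1."""

    pair_id: int
    band: float
    n_spikes: int
    resultant_R: float
    rayleigh_z: float
    p_rayleigh: float
    shuffle_exceed_count: int
    significant: bool
    evaluated: bool


@dataclass
class SessionPair:
    """One beta-neuron pair: per-trial events, LFP and spikes, plus the
    generator's ground-truth labels (empty for recorded data)."""

    pair_id: int
    events: list            # list[TrialEvents]
    lfps: dict              # trial_id -> AnalogTrace
    spikes: dict            # trial_id -> SpikeTrain
    ground_truth: dict = field(default_factory=dict)

    def trials(self, direction: Optional[int] = None,
               delay_class: Optional[str] = None) -> list:
        out = []
        for ev in self.events:
            if direction is not None and ev.direction != direction:
                continue
            if delay_class is not None and ev.delay_class != delay_class:
                continue
            out.append(ev)
        return out


@dataclass
class Session:
    """A collection of beta-neuron pairs sharing one task timing."""

    pairs: list             # list[SessionPair]
    timing: TaskTiming
    meta: dict = field(default_factory=dict)
    version: str = "1"


def fisher_z(rho: float, clip: float = 0.999999) -> float:
    """Variance-stabilizing atanh transform, clipped to avoid infinities
    at |rho| = 1 (clipped values are still monotone in rho)."""
    if not np.isfinite(rho):
        return np.nan
    return float(np.arctanh(np.clip(rho, -clip, clip)))
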