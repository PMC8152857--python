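# Methods

## The question and the analysis logic

Two signals recorded together in motor cortex — LFP beta-band amplitude and
the spike count of a single unit — are both modulated by the events of a
behavioral trial.  A correlation computed across data that span several
trial epochs ("task-related") therefore confounds two very different
situations: an intrinsic moment-to-moment mapping between beta amplitude
and firing rate, and two independent signals that happen to follow the task
in a systematic way.  The package implements the three-part logic that
separates them:

1. the task-related correlation itself (windows pooled across epochs);
2. a trial-shuffling surrogate that keeps each signal's task-locked
   structure but destroys the within-trial pairing — an intrinsic
   relationship survives shuffling, task co-modulation does not;
3. a trial-by-trial correlation inside one fixed pre-cue epoch, where the
   behavioral state is as stationary as the task allows, so any correlation
   reflects intrinsic covariation directly.

Spike-to-beta phase locking is quantified separately as a control for the
local origin of the beta signal: it is a relationship at oscillation-cycle
timescale and is logically independent of an amplitude-to-rate mapping.

## Task model

Trials follow a delayed center-out reaching task.  Fixed epoch durations
(`TaskTiming`): 700 ms from central touch to the temporal cue (TC, 200 ms),
a first delay D1, the spatial cue (SC, 55 ms), a second delay D2 equal to
D1, then GO.  Two presets mirror the two animals' parameterizations:
delays 700/1500 ms ("monkey-T-like") and 1000/2000 ms ("monkey-M-like").
Movement onset is GO plus a reaction time drawn from a normal distribution
truncated to (0, 500] ms — the behavioral allowance; kinematics are not
modeled, movement is only an epoch label.  Analyses use the span from trial
start until 1000 ms after GO.

## Synthetic LFP

Each trial's LFP is 1/f background noise plus beta bursts:

* **Noise** — spectral shaping of white noise with exponent 1 (flattened
  below 1 Hz), unit standard deviation.
* **Bursts** — Hanning-windowed sinusoids at the band center (22 Hz
  default; 19 + 32 Hz as two independent summed processes for the
  monkey-M-like configuration), duration uniform on 200–500 ms, amplitude
  4 a.u. with ±40% uniform per-burst jitter (burst amplitude distributions
  are not well characterized; this is a stated assumption, not a fit).
  Burst *onsets* form a Poisson process of baseline rate 2 bursts/s scaled
  by an epoch-dependent multiplier; beyond that intensity, burst timing is
  not locked to events.  The default profile (pre-TC 1.0, TC 1.0, D1 1.2,
  SC 0.9, D2 0.5, post-GO 0.35, movement 0.2) emulates the canonical
  pattern: beta strong during delays, suppressed after the spatial cue,
  most strongly around movement.  A 600 ms lead-in lets bursts that started
  before trial start overlap it.

## Synthetic spike trains

Inhomogeneous Poisson by thinning (exact for bounded intensity; the bound
is the maximum of the intensity evaluated on the 1 ms grid):

λ(t) = base_rate · rate_profile(epoch) · (1 + tuning_depth·cos(θ_dir − θ_pref))
· (1 + coupling_c·Ã(t)) · (1 + locking_m·cos(φ(t) − locking_phase)), clipped at 0.

Defaults: base rate 10 Hz, cosine tuning depth 0.5, rate profile (pre-TC
1.0, TC 1.0, D1 0.9, SC 1.1, D2 1.6, post-GO 1.9, movement 2.2) emulating
the phasic post-cue increase and movement-time peak of directionally tuned
motor-cortex units.  Ã is the z-scored beta envelope, φ the beta phase of
the *paired* LFP (pairs emulate different-electrode pairing, but injected
coupling must reference the envelope the analysis will see).  The
z-scoring uses envelope mean/SD pooled across the pair's trials: per-trial
z-scoring would remove across-trial envelope variation and make injected
trial-by-trial coupling undetectable by construction.  A standalone
`generate_spike_train` call without pooled statistics falls back to the
supplied trace's own moments.

Calibration properties verified in the tests: realized per-epoch rates
within 5% of the intensity integral; burst durations uniform (KS);
resultant length of spike phases → m/2 under rate ∝ 1 + m·cos φ (the
resultant of that density is exactly m/2).

### What the generator does not emulate

No biophysics (no volume conduction, no spike waveforms), no artifacts or
error trials, no across-electrode envelope decorrelation, no burst-rate or
amplitude drift across a session, no non-Poisson spiking (refractoriness,
bursting).  Passing calibration therefore shows the *analysis machinery* is
correct and well calibrated under realistic task structure — not that real
cortex behaves like the generator.

## Signal processing

* Band-pass: zero-phase (forward–backward) 4th-order Butterworth, band
  center ± 5 Hz, applied per trial with ≥ 500 ms reflection padding that is
  discarded afterward (trials are finite excerpts of a continuous
  recording; padding controls edge transients).
* Envelope/phase: modulus/argument of the analytic signal (Hilbert
  transform), computed on a reflection-padded copy; phase 0 at local maxima
  of the band-passed signal (standard convention).
* Spectra: single-Hanning-taper DFT periodograms, zero-padded to a 1 Hz
  grid; optional 49–51 Hz 8th-order Butterworth band-stop; epoch spectra of
  one LFP normalizable by their joint mean power in 10–40 Hz.  Spectrograms
  use 300 ms windows, 50 ms shifts, values attributed to window centers,
  after a 2 Hz 4th-order high-pass.
* PSTH smoothing: unit-sum Gaussian kernels (length 100 ms / σ 50 ms for
  preferred-direction rate profiles), edges handled by renormalization.

## Segmentation and inclusion rules

300 ms half-open windows `[t0, t0 + 300)` tile the analysis span from trial
start; a trailing partial window is discarded (11/16 windows for the
short/long monkey-T-like timing, 13/19 monkey-M-like).  A spike exactly on
the right edge belongs to the next window (prevents double counting).
Pre-SC and pre-TC epochs are the 300 ms ending exactly at the respective
cue onset.

Preferred direction: maximal trial-averaged smoothed rate at any time from
SC onset to trial end, computed per delay class and maximized over both;
ties break to the lowest direction index; nonpreferred is the opposite
direction (index + 3 mod 6).  Inclusion requires mean rate strictly above
3 Hz across the samples entering each particular correlation.  Trial-by-
trial analyses require at least 8 trials per delay class.

Window subsampling (to equalize statistical power with the trial-by-trial
analysis): repeatedly keep every other window — positions 0, 2, 4, … of the
current kept list, keeping the first element each round — until at most the
target remain, then reintroduce uniformly-without-replacement from the
excluded set.  The "keep the first of each round" convention is arbitrary
but fixed.

## Correlation statistics

Spearman's ρ = Pearson correlation of average ranks (ties get average
ranks).  Two-sided p-values: exact enumeration of all n! pairings for
n ≤ 8, seeded Monte-Carlo permutation (10⁴ draws, add-one correction) for
n ≤ 20, t-approximation above (these thresholds are the package's choice;
empirical type-I error of the t path at α = 0.01, n = 30 is verified to lie
in [0.005, 0.02]).  Constant inputs make ρ undefined; such samples are
flagged and excluded, never counted as significant.  α = 0.01 everywhere,
configurable.  Population shift tests use the two-sided Wilcoxon signed-rank
on Fisher-z-transformed ρ, with |ρ| = 1 clipped to atanh(±0.999999).

CV analyses use SD/mean (sample SD) across the same samples that entered a
correlation; CV is undefined (flagged) at zero mean.

## Shuffle controls

Shuffles permute which trial's envelope is paired with which trial's
counts *within the same direction and delay-class subset*, keeping window
indices aligned, so epoch identity and condition structure are preserved
and the pooled marginals are exactly unchanged.  Window subsampling is
redrawn per repetition, as for the original analysis.  Survival requires
the observed statistic to beat at least ⌈0.99·n_reps⌉ of n_reps shuffles
(990/1000 at the default).  The criterion compares |ρ|: most observed
correlations are negative, so a literal signed "larger ρ" comparison would
be vacuous; the signed variant is recorded alongside for audit.  Under the
generator's null the observed ρ is exchangeable with the shuffled ones, so
the survival rate is a calibrated ≈1% false-positive rate (verified by a
rank-uniformity test and by the null study).

Phase-pairing shuffles let the spikes of trial i read phases from trial
π(i) at identical within-D1 times; D1 durations match within a delay class.

## Phase locking

Phases of all spikes in D1 = [TC offset, SC onset) of long-delay trials,
accumulated across trials; evaluated only for units with strictly more than
50 spikes.  Rayleigh R, z = n·R², and the small-sample-corrected p-series
exp(−z)[1 + (2z − z²)/(4n) − (24z − 132z² + 76z³ − 9z⁴)/(288n²)] are
reported, but significance always derives from the 1000-fold shuffle null,
so the approximation never gates results (it is verified against a
Monte-Carlo uniform null to within 10⁻³ in the relevant tail).  With two
beta bands, each band is evaluated independently per unit.

## Pipeline, seeds, determinism

`run_analysis` composes everything per pair and band, logs every exclusion
with its reason, and emits the report as CSV + JSON with percentages
computed from integer counts at report time.  All randomness flows from a
master seed through named substreams keyed by (pair, band, analysis), so
adding pairs or toggling analyses never changes existing results, and
identical inputs and seeds give byte-identical outputs.  In the default
flow the shuffle control runs on significantly correlated pairs (as in the
screening logic it mirrors); calibration studies run it on all pairs so the
survival fraction is a proper false-positive rate.

## Problem sizes of the calibration studies

Chosen to characterize the pipeline well at desk scale:

* **Null calibration** — 200 pairs, 6 directions × 20 trials per condition
  (≈120 short-delay trials per pair, matching a typical session), only
  short-delay trials generated since only short-delay analyses enter;
  1000 shuffle repetitions per pair, run on every analyzed pair.
* **Coupling recovery** — 100 pairs, 2 opposite directions × 50 trials
  (100 trials per delay class; 2-direction sessions are themselves part of
  the emulated protocol), `coupling_c = 1`.
* **Phase locking** — 100 locked units (m = 0.5, locking phase π/2) and 250
  unlocked units, 20 long-delay trials each (~300–500 D1 spikes per unit).

## Known limitations

The generator's epoch profiles are stylized step functions, not measured
peri-event time courses; envelope-to-rate coupling is injected linearly in
the z-scored envelope, which is one of many possible coupling shapes; the
Spearman p-value policy differs in detail from any specific legacy
implementation (the shuffle-based decisions do not depend on it); and the
two-band configuration treats the bands as independent, whereas real low-
and high-beta bands can interact.
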