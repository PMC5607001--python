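# Methods

This note documents the models behind `lamdec`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions used throughout.

## Time and windows

All event and spike times are integer milliseconds on a single session
clock; every analysis window is half-open `[t0, t1)`.  Firing rates come
from 1-ms binned spike counts passed through a *causal* boxcar: the rate
at `t` is `(1000/w) ×` the count in `(t − w, t]`, so a spike can only
influence bins at or after its own time.  `w` is 75 ms for single-unit
displays and 50 ms for every population analysis.  Edge bins use the full
divisor (no partial-window correction).  Two masking rules prevent
cross-contamination between stimulus- and movement-locked activity:
cue-aligned rates are masked (NaN) from `RT − 100` ms onward, and
movement-aligned rates before `−RT` (i.e., before cue onset).  Trials
flagged as changes of mind (~2.5%) are excluded from every average.

## Behavioral model

Accuracy versus coherence is fit by weighted nonlinear least squares to
the cumulative Weibull `p(c) = 1 − 0.5·exp(−(c/α)^γ)` on per-level
proportions, weighting levels by trial count, with a multi-start over
`γ ∈ {0.5, 1, 2, 4}` to avoid local minima (a binomial-likelihood fit
would also be defensible; least squares was chosen for transparency and
is validated by parameter-recovery tests).  `α` is the coherence at 81.6%
correct.  Mean RT is regressed on `ln(c)` including error trials.

## Synthetic sessions

The generator's defaults define the study conditions; they are fixed, not
tuning knobs.

**Behavior.**  Choices and decision times come from a drift-diffusion
model `dV = μ dt + dW` between absorbing bounds at `A = 1` (red) and `0`
(green), starting at `z = 0.5`, Euler step 1 ms with unit-variance
noise per second.  Because a discrete-time walk can cross a bound inside
a step, each step also samples the Brownian-bridge crossing probability
`exp(−2(b − v0)(b − v1)/dt)`; without this correction simulated absorption
probabilities are biased above the closed-form first-passage law by more
than Monte-Carlo error.  Drift magnitude is `12 × SC/100` per second
(trial-to-trial SD 0.5), which places the synthetic psychometric
threshold near 12–14% coherence — between the thresholds typical of
trained macaques on this task.  Non-decision time is Gaussian
(300 ± 40 ms); a `d_ms` parameter can shift it for one response.
Non-absorbing paths (cap 5 s) are resampled and counted.  The seven
default coherences derive from red-square counts
{117, 126, 139, 156, 177, 199, 214} on the 225-square board:
{4.0, 12.0, 23.6, 38.7, 57.3, 76.9, 90.2}% — the printed task extremes
with roughly log-spaced levels between.  Hold periods are uniform
400–900 ms (a truncated-exponential 400–800 ms variant is provided; the
two correspond to the two animals' protocols and neither is canonical).

**Firing-rate archetypes.**  Each unit is one of three archetypes:

* *increased*: baseline 15 Hz, then from cue + 150 ms a coherence-
  independent ramp of +65 Hz/s plus a choice-selective ramp whose
  preferred/non-preferred difference grows at 50 Hz/s per 100% coherence;
* *decreased*: baseline 38 Hz, ramp −95 Hz/s, with a constant ±10 Hz
  choice difference appearing only 100 ms before movement;
* *perimovement*: flat 10 Hz until a +25 Hz burst 150 ms before
  movement, with the same late ±10 Hz choice difference.

Rates are clipped at zero.  The split into a coherence-independent
visuomotor ramp and a coherence-proportional choice ramp is deliberate: a
ramp whose slope scales only with coherence cannot produce the defining
RT correlation of the increased/decreased classes, because high coherence
simultaneously steepens the ramp and shortens the RT and the two effects
cancel in the −600..−200 ms epoch, leaving Poisson noise dominant.  The
ramp magnitudes were calibrated once so that, at 800 trials, the
visuomotor index of increased/decreased units sits near the |r| ≈ 0.3
operating point at which classification recovery is assessed; the choice
ramp gives the characteristic coherence-ordered build-up of selectivity.

**Spiking.**  Spikes are an inhomogeneous Poisson process drawn by
thinning — the simplest model whose PSTHs converge to the intensity; its
correctness is checked by the time-rescaling theorem (rescaled ISIs vs.
unit exponential).  `generate_session` additionally imposes a 3-ms dead
time, since a pure Poisson train at these rates would have ~4% of ISIs
within a 2-ms refractory period and be graded "multi-unit" by the
isolation rule (ISI violations ≥ 1.5%).

**Laminar structure.**  Units are placed on a 16-contact probe
(150 µm spacing; depth of contact `e` = insertion depth + 0.15·(e−1) mm).
The depth rule interpolates archetype probabilities from a superficial
mix (0.72/0.08/0.20 increased/decreased/perimovement) to a deep mix
(0.18/0.32/0.50), chosen so the electrode-averaged index falls from
about +0.2 superficially to about 0 at depth — the laminar contrast the
analyses are designed to detect.  A `deep_extra_latency_ms` option delays
the cue latency of deep units, providing a known decoding-latency ground
truth.  Kinematics are a sigmoidal reach trace starting at movement onset
and jittered fixation eye traces, sampled at 10 ms.

**What the generator does not emulate:** correlated noise between
simultaneously recorded units, non-Poisson spiking statistics (bursting,
adaptation), urgency-gating dynamics, drifting baselines, change-of-mind
kinematics (flagged trials are ordinary trials with a label), and
electrode drift.  Passing recovery tests therefore demonstrates estimator
correctness under the assumed generative structure, not robustness to
every property of real recordings.

## Visuomotor index

Per trial, the hold-period baseline (mean rate in the 200 ms before cue)
is subtracted from the mean rate in the −600..−200 ms pre-movement epoch
(window start truncated to −RT for RT < 600 ms, so pre-cue activity never
enters); the index is the Pearson correlation of this quantity with RT
across all trials, both reach directions pooled.  Significance uses a 90%
percentile bootstrap over trials (1000 resamples; ~10% of null units are
expected to exclude zero by construction, verified by calibration).  A
rank (Spearman) variant is available.  The Bayes factor for a nonzero
correlation is a Jeffreys–Zellner–Siow test computed by numerically
integrating the Zellner–Siow g-prior marginal likelihood (log-domain
trapezoid on a log-spaced grid, prior scale 1/√2); at scale 1 it matches
the standard reference implementation to 0.1%.  Whether baseline
subtraction should be per-trial or per-session is ambiguous; per-trial is
the default, and since the Pearson correlation is invariant to constant
shifts the choice only matters through trial-to-trial baseline noise.

## Choice selectivity and discrimination time

The population selectivity signal is, per unit, `|mean_L(t) − mean_R(t)|`
minus the same quantity in the hold period, averaged across units (SEM
over units).  Note the folding bias inherent in this estimator: under
pure noise `E|L − R| = σ√(2/π) > 0`, which the hold subtraction removes
at baseline but which compresses slopes when per-unit SNR is low.  For
slope analyses, each coherence's window (150–350 ms post-cue) is
truncated at that coherence's median RT − 100 ms; beyond it most trials
are masked and the rising noise floor would inflate the slope.  The
build-up slope per coherence is an OLS of the signal on time; a
second-level regression of slopes on coherence gives the coherence
dependence, tested against a null that shuffles coherence labels across
each unit's curves (200 shuffles by default; the count is not stated in
the source conventions, so it is configurable).

Population discrimination time: at each 1-ms post-cue bin, a paired
t-test compares units' selectivity with their own hold-period (−500..0 ms
pre-cue) selectivity; p-values are Benjamini–Hochberg corrected across
bins, and the latency is the first bin opening a run of ≥ 50 consecutive
significant milliseconds ("at least 50 ms" read as 50 consecutive 1-ms
bins).  Its error bar is the SD over 50 surrogate data sets obtained by
resampling trials within unit (resampling within choice, so both
directions stay present).  The single-unit variant thresholds a unit's
selectivity at the 95th percentile of its bootstrapped hold-period
selectivity, with the same 50-ms persistence rule.

## Population structure

For PCA and clustering, each unit's preferred/non-preferred
trial-averaged rates (−100..+600 ms around cue; preference from a t-test
on rates in `[move−150, move+50)`) are concatenated and divided by the
unit's across-condition range ("softmax" normalization), so high-rate
units do not dominate.  Uniformity of 2-D loadings is tested by octant
χ² (skipped below 40 units) and by PAIRS: each point's mean angle to its
3 angularly nearest neighbors (neighbor count unstated in the source
conventions; 3 is the default, configurable), median over points,
compared two-sidedly to medians of standard-Gaussian samples of equal
size.  The gap statistic uses uniform reference draws in the data's
principal-axis bounding box (B = 50) and selects the smallest k whose gap
is within one SE of the maximum — the first k at which the separation
from the reference has saturated.  (The textbook "first k with
gap(k) ≥ gap(k+1) − s" rule fires spuriously at k = 1 on well-separated
clusters, where the gap curve is flat near zero before jumping.)

Alignment offsets: trials are iteratively cross-correlated (FFT-based,
peak lag within ±300 ms) against the leave-one-out trial average, shifted,
and re-averaged until the average's variance changes < 1% (cap 25
iterations).  Offsets are reported with the convention that a trial whose
features lead the template needs a positive shift; movement-aligned, this
makes cue-locked units' offsets correlate positively with RT.  The sign
of the offset–RT correlation is flipped for units whose perimovement rate
(last 100 ms) is below their rate in the −800..−700 ms reference epoch,
recovering the direction of rate change the offset method is blind to.

## Laminar analyses

The index-versus-depth profile averages unit indices per electrode within
session, then across sessions, and fits a cubic `ax³ + bx² + cx + d` in
depth; the p-value is the fraction of 1000 within-session shuffles of
index values whose fit R² exceeds the observed one.  Decoding uses a
Gaussian class-conditional classifier with per-feature variance pooled
across classes — a naive-Bayes rule whose equal-covariance assumption
makes the boundary linear — with uniform class priors, because empirical
priors let class imbalance alone push "accuracy" past the 55% latency
threshold before the stimulus appears.  Features are 50-ms boxcar counts
retrained every 2 ms, 10-fold CV stratified by choice, RTs restricted to
300–1000 ms, same trials for both compartments, the larger unit pool
subsampled to the smaller (10 repeats, averaged).  The latency is the
first post-cue time accuracy stays above 55% for ≥ 30 ms; the post-cue
restriction and the persistence requirement suppress threshold crossings
by correlated noise excursions (the 50-ms feature window makes accuracy
noise long-lived).  The benefit `t_deep − t_superficial` is the mean over
10,000 bootstrap resamples of sessions, with p the fraction of resampled
benefits below zero.

## Regression controls

At each time bin (default every 25 ms along the 50-ms-boxcar rate — finer
stepping adds no information at this smoothing), single-trial rate is
regressed by OLS on z-scored predictors: coherence, choice, chosen color,
RT, hand x/y and eye x/y at that bin (interpolated from the sampled
traces), hand speed, and the RT × coherence and RT × choice interactions
(interactions formed from raw values, then z-scored).  Zero-variance
predictors are dropped and reported; a design-matrix condition number
above 10⁴ sets a collinearity flag.  Per-coefficient 95% CIs define
significance; population counts of significant units per bin are read
against the 5% binomial chance band.

## Numerical and testing notes

Simulation sizes in the test suite (e.g., 1000 null units for CI
calibration, 200 null populations for false-detection control, 100 seeds
for gap-statistic selection, 10 sessions for the decoding-latency
pipeline) were chosen to give tight binomial/Monte-Carlo bands while
keeping the full suite comfortably under typical CI budgets.  Estimator
recovery tests that require high per-unit SNR (the selectivity-slope
generative constant) use constructed rate matrices with long RTs so that
masking and noise folding do not confound the quantity under test; the
same estimators are additionally exercised qualitatively on full
generated sessions.  Degenerate inputs follow one rule: impossible
configurations raise (`ValueError`/`ValidationError` listing offending
rows), while statistically undefined results return flagged values
(`defined=False`, `degenerate=True`, NaN) rather than raising.
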