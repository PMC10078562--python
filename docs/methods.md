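# Methods

`posturo` implements the analysis chain of a quiet-standing CO2-challenge
posturography experiment: sway path lengths and local dynamic stability of
centre-of-pressure (COP) trajectories, breathing-rate extraction from a
respiration transducer, and the repeated-measures inference layer that
compares inhalation conditions. Because the deposited cohort data are not
required, a synthetic-cohort generator reproduces the study's design with
injectable, known condition effects, so every stage can be validated
end to end.

## Sway path metrics

For a trial of N samples per axis, the medio-lateral (ML) and
anterior-posterior (AP) sway path lengths are the summed absolute
increments `sum |X_{i+1} - X_i|` and `sum |Y_{i+1} - Y_i|`, and the total
path is `sum sqrt(dX^2 + dY^2)`, over `n = N - 1` increments. Increments
enter in absolute value: without it the per-axis sums telescope to the
end-to-end displacement, which is not a path length. COP series are
deliberately not filtered before any sway or stability computation, since
low-pass filtering removes genuine high-frequency sway content and
deflates both measures. The metrics are translation invariant and scale
equivariant; `n_increments` is recorded so results for trials of any
length are interpretable. A 30-s trial at the default 50 Hz yields 1499
increments.

## Local dynamic stability (largest Lyapunov exponent)

The scalar COP series for one direction is embedded by the method of
time delays, `X(t) = [x(t), x(t+T), ..., x(t+(d_E-1)T)]`.

**Delay selection.** `T` is taken, per trial and per direction, from the
first minimum of the average mutual information (AMI) between the series
and its lagged copy. AMI is computed from a joint histogram on a 64x64
equal-width grid (nats). Because the AMI valley of band-limited signals
is flat to within histogram-estimator jitter, the raw "first lag that is
a pointwise local minimum" rule is unstable; instead the curve is lightly
smoothed (5-point moving average) and the first *significant* valley is
detected: the search confirms a valley when the curve has risen at least
`min_tol` (default 0.05 nats) above its running minimum, and reports the
centre of the plateau of lags within `min_tol` of that minimum. For a
quarter-period-symmetric valley (a sine) this returns the quarter period;
for signals whose AMI decays monotonically (mean-reverting noise) no
valley exists and the fallback is the first lag where AMI drops below
`AMI(1)/e`, else `max_lag` with a flag. A degenerate corner worth knowing
about: a sinusoid whose period divides the sampling grid exactly visits
only `period` distinct values, which makes the binned AMI lag-independent
and nearest-neighbour geometry meaningless; validation fixtures therefore
use a slightly incommensurate period so the phases are dense, as they are
for any real signal.

**Dimension selection.** Global false nearest neighbours (Kennel
criterion): for each candidate dimension `d` the nearest neighbour of
every embedded point is found (KD-tree); the neighbour is false if the
added `(d+1)`-th coordinate inflates the pair distance by a factor above
`r_tol = 15`, or pushes it beyond `a_tol = 2` times the series standard
deviation. The chosen `d_E` is the smallest dimension with a false
fraction below 1%; saturation at `max_dim` is flagged, never silent.
Pairs whose joint distance sits at the floating-point noise floor
(periodic revisits) are excluded from the false count — their distance
ratio is numerical noise. The analysis default is the study's fixed
`d_E = 6` for COP; FNN is available via `dimension="AUTO"`.

**Divergence and slope.** Following the Rosenstein nearest-neighbour
method, each embedded point is paired with its nearest neighbour subject
to a Theiler exclusion equal to the signal's mean period — the
reciprocal of the power-weighted mean frequency of the periodogram (DC
excluded) — converted to samples. The pair distance `d_j(i)` is tracked
`i` steps forward; the curve value at time `i/fs` is the mean of
`ln d_j(i)` over pairs still inside the series (zero-distance pairs
excluded). The largest Lyapunov exponent is the ordinary-least-squares
slope of this curve over the fit window, reported in 1/s. For COP trials
the window is 0-0.75 s, the study's convention. For long chaotic
validation fixtures the fit window is placed on the linear region after
the brief neighbour-alignment transient (Lorenz: 0.5-2.5 time units);
fitting from zero on such fixtures mixes the transient into the slope.
The exclusion window is capped at a third of the embedded point count so
short trials of slow signals retain admissible neighbour pairs. An
increased exponent means faster divergence, i.e. lower local dynamic
stability. The whole stage is seed-free and bit-reproducible; scaling a
series by `c` shifts the curve by `ln c` and leaves the slope unchanged.

**Independent oracle.** The Rosenstein estimator is validated against
`lyapunov_oracle`, which shares no code with it: for the logistic map the
exact orbit average of `ln |r(1-2x)|` (analytic `ln 2` at `r = 4`); for
the Lorenz system the Benettin tangent-space method, integrating the
variational equations alongside the flow with periodic renormalisation
(0.906 per time unit at the classical parameters).

## Respiration processing

The transducer trace (2000 Hz) is polyphase-resampled to 100 Hz
(`resample_poly`, linear-extension padding so constants survive) and a
linear-phase FIR band-pass (0.5-1 Hz, 8000 taps, Hamming design, group
delay compensated; an even tap count is promoted to odd for an integer
delay) is available as the documented preprocessing step. The vendor's
`Q = 0.70700` has no FIR meaning and is carried as metadata only.

Breathing rate in a balance window: the window is smoothed with a 25-ms
moving average (baseline tracking), positive peaks are detected with a
prominence threshold of 5% of the window's peak-to-peak range (a
range-relative hysteresis, so the estimate is invariant to amplitude
scaling), inter-peak intervals outside the physiological 6-20
breaths/min band are discarded, and the rate is 60 over the mean
retained interval. Fewer than two plausible peaks is an explicit
undefined-rate error, never a zero. One deliberate reconciliation: the
documented 0.5-1 Hz passband lies *above* the fundamental of quiet
breathing (6-20 breaths/min = 0.1-0.33 Hz), so the pipeline's rate
detector runs on the resampled trace rather than the band-passed one —
band-passing first would suppress exactly the oscillation being counted.
The filter stage is still implemented and validated against its design
criteria (unit passband gain at 0.75 Hz, over 40 dB attenuation at
0.05 Hz). The "during inhalation" rate for the 2x2 breathing-rate ANOVA
is the mean across the three balance windows; the post-inhalation window
supplies the second level.

## Statistics

Outcomes are aggregated to one value per subject x inhalation type x
inhalation time (mean over the up-to-5 repetitions, with the repetition
count recorded; an empty cell is an error naming the cell). Before
aggregation into the ANOVA, each outcome is screened once for outlier
subjects: a subject is removed when its value lies strictly more than
2.5 sample standard deviations (ddof 1) from the sample mean; a
zero-variance sample removes nobody, and there is no re-screening.

The two-way fully-within ANOVA uses the classical decomposition with
subjects as the random blocking factor; each effect is tested against
its own effect-by-subject interaction. Greenhouse-Geisser epsilon is
computed from the covariance of the orthonormalised (Helmert) contrasts
— Kronecker products of the factor contrasts for the interaction —
clipped to `[1/df, 1]`; it is exactly 1 for two-level factors, so the
correction only bites where sphericity is estimable. Both raw and
corrected degrees of freedom and p-values are always reported. Effect
size is partial eta squared, `F df1 / (F df1 + df2)`, which the
implementation also maintains as an internal identity to 1e-12. F-test
p-values are the standard upper-tail probabilities (the directional test
for an F statistic); Pearson change-score correlations report one-tailed
p in the direction of the observed association and an Evans verbal band
on |r| (.00-.19 very weak, .20-.39 weak, .40-.59 moderate, .60-.79
strong, .80-1.0 very strong). Pairwise follow-up for significant effects
is Bonferroni: all level pairs for a main effect (6 pairs for four time
points), and the per-time condition contrasts for the interaction
(4 pairs), with `p_adj = min(1, m p)`.

The implementation is cross-checked in the test suite against
`pingouin.rm_anova` (agreement to 1e-9 on F, p, epsilon, eta_p2) and
calibrated on 2000 simulated null cohorts (10 subjects, 2x4 design,
compound-symmetric covariance): each effect's rejection rate at
alpha = 0.05 falls inside the 95% binomial interval.

## Synthetic cohort generator

The generator emulates the study conditions: 10 subjects x {air, 7.5%
CO2} x {5, 10, 15 min, post-inhalation} x 5 repetitions of 30-s COP
trials at 50 Hz, plus one respiration trace per design cell (2000 Hz).
Every series is a pure function of the root seed (default 20221006) and
the design labels, split per trial via `SeedSequence`.

Each COP axis is the sum of two components:

* **Stochastic baseline** — an exact-discretisation Ornstein-Uhlenbeck
  process (reversion 1/s, diffusion `ou_noise_scale` mm/sqrt(s) per
  condition) smoothed by a zero-phase 4th-order Butterworth low-pass at
  0.3 Hz with generous burn-in margins. The smoothing stands in for the
  mechanical low-pass of the standing body; an unsmoothed OU path has
  white increments whose instantaneous decorrelation dominates the
  short-time divergence curve and masks the chaotic component entirely.
  The diffusion is the sway-path dial.
* **Chaotic component** — a per-trial Lorenz trajectory (classical
  parameters, random initial state, RK4 at dt 0.005, sampled at 0.01
  time units per COP sample so divergence stays below saturation within
  the 0.75-s fit window), variance-normalised and scaled by
  `chaos_blend_gain` (mm). The Lorenz x coordinate feeds AP, y feeds ML.
  The gain is the stability dial: the measured AP exponent increases
  monotonically with it under the full per-trial AMI + Rosenstein
  pipeline.

Both dials are multiplied by a per-subject log-normal factor
(sigma 0.2), keeping outcomes positive with multiplicative heterogeneity.
Defaults inject the study's qualitative effects: CO2 diffusion 1.2x air
and CO2 gain 1.5x air, which the recovery tests resolve with >= 100
trials per condition. Under these defaults the per-trial AMI delays on
COP fall in the several-tens-of-samples regime, matching the scale of
delay the study reports descriptively.

Respiration traces are laid down breath by breath: cycle durations are
jittered with CV `0.5 * noise` and renormalised so the realised long-run
rate equals the nominal rate exactly, amplitudes with CV `1.5 * noise`
(resting breathing varies far more in depth than in timing), plus an
additive noise floor of `0.2 * noise` relative amplitude. Condition
means default to air 12.1 / 15.0 CO2 breaths/min during inhalation and
~11 post-inhalation, with a per-subject offset (sd 1 breath/min) clipped
to the detectable band.

A separate cell-level null generator (subject random effect plus iid
noise) supplies the thousands of cohorts needed for type-I-error
calibration; running the full signal pipeline 2000 times would add
hours of computation without changing what the calibration measures,
since the ANOVA consumes only cell means.

**What the generator does not emulate:** closed-loop postural control
(no inverted-pendulum mechanics, no sensory feedback), non-stationarity
within a trial, drifts or artifacts in the respiration trace, and any
coupling between breathing and sway beyond what the injected condition
effects induce. Passing recovery tests therefore demonstrate that the
estimators detect effects of the injected kind at the study's design
size — not that the study's physiological effect sizes are correct.

## Numerical choices and degenerate inputs

* AMI: constant series raise a degeneracy error; `min_tol` 0.05 nats;
  64 bins by default (the iid-noise bias `(bins-1)^2 / 2N` stays well
  below `min_tol` at the series lengths used).
* FNN: `r_tol` 15, `a_tol` 2, threshold 1%, saturation flagged.
* Rosenstein: >= 100 embedded points required; zero initial-distance
  pairs dropped; all pairs excluded is an error; slope fit inclusive of
  both window endpoints.
* ANOVA: zero error variance raises unless the effect sum of squares is
  exactly zero, which reports F = 0.
* Outlier screen: exact-boundary values (exactly 2.5 sd) are retained.
* File formats: plain text, full float precision (`repr` out,
  round-trip parsing in), uniform-time validation to 1e-6 s; readers
  reject rather than coerce.

## Problem sizes used by the validation entry points

The test suite and `scripts/acceptance.py` use 10^4 logistic samples,
3x10^4 Lorenz samples (10^6 Benettin steps in the script, 2x10^5 in the
suite), 500 Gaussian-walk replicates, 2000 null cohorts, and synthetic
cohorts of 240-400 trials (>= 100 per condition) for effect-direction
recovery — sizes chosen so each estimate's Monte-Carlo error is small
against the tolerance it is checked at.

## Known limitations

* The Rosenstein exponent of a noisy stochastic signal is an effective
  divergence rate, not a dynamical invariant; its value depends on the
  embedding, the Theiler window and the fit window. Comparisons are
  meaningful within a fixed protocol, which is how both the study and
  this package use it.
* The breathing-rate detector reproduces documented settings of the
  acquisition software, not the vendor's proprietary algorithm
  bit-for-bit.
* The 2x2 breathing-rate design collapses three during-inhalation
  windows into one level; alternatives (e.g. treating windows as a
  nested factor) are out of scope.
* With cell-level outcomes near the 20 breaths/min detector bound,
  interval censoring biases rates slightly downward; the generator's
  timing CV keeps this negligible in the validated range (8-18
  breaths/min, noise <= 0.1, absolute error <= 0.5 breaths/min).
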