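# Methods

This note documents the models and estimators in `prepexec`, the
synthetic data they are validated on, the defaults and why they were
chosen, and what passing the test suite does and does not establish.

## The scientific question

During delayed reaching, motor-cortical population activity occupies
*preparatory* dimensions (condition-selective during the delay),
*movement* dimensions (condition-selective during execution, orthogonal
to the preparatory ones), and a direction-independent *trigger*
dimension whose change precedes movement onset. When a reach target
jumps after the go cue but before movement, the correction could either
be handled entirely within whatever dimensions are active at the time
("direct response") or re-engage the preparatory dimensions even during
movement ("always prepare"). The pipeline quantifies (i) how behavior
transitions from first-target to final-target initiation as a function
of jump-to-onset latency, (ii) whether the decoded trigger event
predicts that transition trial by trial, and (iii) whether
preparatory-dimension activity re-emerges after late jumps.

## Rate estimation and normalization

Single-trial firing rates are spike trains convolved with a Gaussian
kernel (s.d. 30 ms), evaluated analytically on a 10 ms grid; near trial
boundaries the kernel is renormalized by its mass inside the recorded
window so each spike integrates to one (conservation holds to <1e-3 for
interior spikes). Each unit is soft-normalized: divided by
max(s.d. of its rate concatenated over all trials, 1), the floor
preventing inflation of near-silent units. Movement onset is the time at
which hand speed, traced backward from its peak, last falls below 5% of
the peak (linearly interpolated; speed from central differences with a
10 ms smoothing — the raw derivative is noisy at 5 ms sampling and no
filter is prescribed by convention, so the mildest one is used).

## Trigger decoder

A linear SVM separates population vectors sampled every 10 ms in
[−360, −180) ms before movement onset from vectors in [−120, +60) ms
(half-open windows, 18 timepoints each), pooled over all non-jump reach
directions; 10% of non-jump trials are held out for timepoint accuracy.
The regularization constant defaults to C = 1e-3: with ~10⁴ highly
noisy single-timepoint vectors, near-hard-margin solutions fit support
vectors' noise and the recovered axis wobbles by 20–30° around the true
trigger direction, while a strongly regularized soft margin (which
approaches the class-mean discriminant) recovers it to ~15° with
identical held-out accuracy and crossing-time error. C is exposed for
sensitivity analyses. Weights are sign-canonicalized (peri-movement
decision values positive) and scaled to unit norm, which leaves the zero
crossing invariant. The per-trial trigger event is the first upward zero
crossing of the decision value after the go cue, linearly interpolated
between grid points; absence of a crossing is a valid outcome, not an
error.

## Subspace identification

Non-jump condition averages enter two n × (conditions·timepoints)
matrices: the delay epoch (0–300 ms after target onset, trials with
delays ≥ 300 ms) and the movement epoch (0–300 ms after movement
onset; the epoch end is a package choice mirroring the delay epoch's
length). Both are projected into the null space of the trigger dimension
(reducing to n−1 rows) and row-centered. Subspace dimensionalities
default to the smallest PCA rank explaining strictly more than 70% of
epoch variance. The joint objective — mean of the two normalized
captured variances, each divided by the sum of its covariance's top-d
eigenvalues — is maximized over joint orthonormal frames
[Q_prep | Q_move] by Riemannian gradient ascent: Euclidean gradient
projected to the Stiefel tangent space, QR retraction, backtracking line
search (monotone by construction), convergence at objective gain
< 1e-9, ten seeded random starts plus a spectral start (top prep
eigenvectors, then top movement eigenvectors orthogonalized against
them). The objective is bounded by 1, attained exactly iff each basis
spans its covariance's top eigenspace; block-disjoint covariances
therefore make a closed-form correctness check. Only subspaces, not
bases, are identified; all comparisons use principal angles.

## Distances and the re-engagement test

For each jump condition the pipeline averages jump trials by their
behavioral initial-direction label (normalized initial angle below/above
zero) and computes per-timepoint Euclidean distances to the non-jump
final-target trajectory within each subspace, per alignment (target
onset, go cue, movement onset). The test statistic is the mean
preparatory-space distance 0–200 ms after movement onset, compared
across conditions between corrected-jump reaches and the non-jump
first-vs-final baseline with a two-sided Wilcoxon rank-sum (exact when
both groups are ≤25 and untied). Because jump-condition averages use
few trials, their distances carry a positive noise bias of order
3σ²/2μ; the non-jump baseline is therefore computed from a
**trial-count-matched** random subsample of non-jump trials, giving both
distributions the same bias. Without matching, the comparison rejects
under the null at several times the nominal rate whenever the baseline
distance is small.

## The synthetic session generator

The generator emulates the task and the population structure the
analysis assumes; its defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_units / n_trials | 60 / 1000 | one "array day" of simultaneous units |
| delay_range | 0–0.9 s | uniform delay between target onset and go cue |
| p_jump | 0.2 | jump-trial fraction; jump time uniform in (go, onset) |
| rt_mean / rt_sd | 0.30 / 0.05 s | reaction time, clipped to [0.2, 0.45] |
| trigger_lead | 0.150 s | trigger zero crossing precedes movement onset |
| trigger_jitter | 0.010 s | logistic scale of crossing jitter |
| d_prep / d_move | 3 / 3 | latent subspace dimensions |
| prep/move/trig amplitude | 18/15/15 sp/s × snr | population modulation scales |
| snr | 2.0 | overall modulation vs Poisson noise floor |
| baseline_range | 10–20 sp/s | keeps the softplus link near-linear |
| prep_residual | 0.15 | preparatory envelope decays to this fraction |
| pattern_amp_jitter | 0.2 | lognormal tuning heterogeneity across conditions |
| correction_latency | 0.100 s | neural re-targeting delay after a jump |
| correction_gain | 1.5 | re-engagement amplitude relative to delay-period |

Latents are piecewise-smooth ramps (≈80 ms rise). Preparatory latents
ramp to a per-condition pattern on a ring of harmonics (equal variance
per dimension, then jittered per condition), contract to
`prep_residual` starting at the trigger crossing, and — in the default
always-prepare mode — re-target toward the final-target pattern
beginning `correction_latency` after a jump, with a disproportionate
amplitude (`correction_gain`), regardless of how late the jump occurs.
In `direct_response=True` mode re-targeting happens only if the
correction begins before the trigger crossing; late corrections then
occur in movement dimensions alone, giving the pipeline a negative
control. The trigger latent is a logistic step (τ = 25 ms) crossing
zero at onset − trigger_lead + ε with ε ~ Logistic(0, trigger_jitter).
A jump trial is initiated toward the first target exactly when the
crossing precedes the jump, so
P(final | latency L) = expit((L − lead)/jitter): the behavioral
psychometric curve is exactly logistic with its 50% point at
`trigger_lead` — the closed form the sigmoid-recovery tests check
against. Rates are softplus(baseline + orthonormal mixture of latents);
spikes are inhomogeneous Poisson at 1 ms resolution. Hand paths are
minimum-jerk reaches; corrected trials blend to the final target's path
from `correction_latency + kinematic_delay` after the jump, with a
direction perturbation (s.d. 8°) that decays with distance so endpoints
land on the target.

Several defaults were set by matching the regimes real recordings show:
baselines of 10–20 sp/s keep softplus near-linear (lower baselines
rectify strongly driven units and systematically tilt recovered
subspaces); the amplitude scales put the delay-epoch preparatory share
of cross-condition variance near 0.7 and the movement-epoch movement
share near 0.8; `correction_gain` reflects that observed preparatory
jump responses exceed the separation between non-jump trajectories;
`prep_residual` keeps a small preparatory separation alive during
movement, as distance traces from real data show.

### What the generator does not emulate

Trial-to-trial latent variability beyond event timing; non-Poisson
spiking (refractoriness, bursting); unit instabilities and drift;
correlated (shared) noise beyond the latent structure itself; eye
movements; EMG; the optional anti-directional correction transient is
off by default (`overshoot=True` enables a stylized version). Passing
recovery tests on this generator shows the estimators are correct and
well-calibrated under the assumed model — not that real cortex obeys
the model.

## Numerical choices and degenerate inputs

Sigmoid fits: bounded least squares (asymptotes in [−1.5, 0] and
[0, 1.5], tolerating overshoot angles), five deterministic t50 starts
across the latency range; data with all angles on one side of zero are
a fit error (no transition), as are <8 trials. Bootstrap CIs: 1000
trial resamples by default (percentile 95%). ANOVA with zero variance
everywhere returns F = 0, p = 1. The rank-sum test returns p = 1 for
fully tied data. Kurtosis is the non-excess fourth standardized moment;
constant weight vectors are an error. The optimizer rejects non-PSD
covariances (tolerance 1e-8 relative) and reports per-term captured
variances. `choose_dims` resolves a tie at the threshold upward
("over 70%" is strict). Session bundles are HDF5 with object
timestamps disabled, so identical sessions produce byte-identical
files.

## Problem sizes in the test suite

The acceptance-style tests run 20 default sessions for subspace and
trigger recovery, 50 always-prepare plus 50 direct-response sessions
(30 units, 700 trials, eight jump pairs spanning 45–180°) for
hypothesis discrimination, 10 random covariance pairs against the grid
oracle, and 100 seeds for behavioral CI-filter monotonicity; these sizes
give stable pass/fail margins while keeping the default suite's total
runtime modest.

## Known limitations

- The trigger-axis comparison maps ground truth through the same
  per-unit normalization the decoder saw; with strongly heterogeneous
  units the decoder direction and the latent axis image can differ by a
  few degrees even at high SNR (whitening vs. normalization mismatch).
- Subspace recovery degrades gracefully but systematically when one
  epoch's covariance contains variance from the other epoch's
  subspace (e.g. large preparatory residuals during movement): the
  joint objective then prefers slightly tilted frames.
- The exact movement-epoch end time is a convention (300 ms); variance
  shares shift by a few percent for 200–400 ms windows.
- Behavioral labels come from the sign of the normalized initial angle;
  with very large angle noise (>20° s.d.) label errors would blur the
  jump-condition averages.
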