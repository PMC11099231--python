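# Methods

`driftdecode` re-implements, as a tested pipeline, a two-track analysis of
how task-irrelevant distractors affect categorical decision-making: a
hierarchical Bayesian drift-diffusion model (HDDM) of choice/RT data, and a
single-trial sliding-window EEG discrimination analysis with forward-model
topographies, temporal clustering, and cluster-based group statistics.
Because the pipeline is exercised on synthetic data, this note documents
both the models and what the generator does and does not emulate.

## Study design emulated by the generator

Each synthetic participant completes a visual and/or auditory
categorization task under three conditions: no distractor (ND), auditory
distractor (AD), and visual distractor (VD).  The ND block comes first
(baseline), followed by AD/VD blocks in randomized order.  Default trial
counts are 60 (ND) and 120 (AD, VD) per task.  The printed total in the
source design description (240) is inconsistent with 60+120+120; counts are
therefore explicit parameters and never asserted to sum to a fixed total.
Auditory targets occupy one of six positions in a sound sequence of six
250 ms sounds separated by 50 ms gaps (1,750 ms total); the auditory RT
clock starts at target onset, `(position-1) * 300` ms into the sequence.
Congruency of the distractor with the target is generated and balanced but
has no effect on the generative parameters (the design treats it as a
random factor with no effect).

## Drift-diffusion core

The decision model is the 4-parameter Wiener diffusion: evidence starts at
`w = z*a` between absorbing boundaries 0 and `a`, drifts at rate `v` with
unit diffusion coefficient, and the observed RT adds a non-decision offset
`t`.  No inter-trial variability parameters are included.  Parameters and
units:

| parameter | meaning | unit | typical range used |
|---|---|---|---|
| `v` | drift rate | evidence/s | 0.5 – 3 |
| `a` | boundary separation | evidence | 0.8 – 2 |
| `z` | relative start point | – | (0, 1), 0.5 = unbiased |
| `t` | non-decision time | s | 0.2 – 0.5 |

The first-passage-time density uses the dual series expansion in
normalized time `t' = u/a²` with automatic small-time/large-time selection
and truncation bounds chosen for an error below `err_tol` (default 1e-7)
in the normalized density.  Closed forms used as oracles in the tests: the
upper-boundary absorption probability `(1-e^{-2vw})/(1-e^{-2va})` and the
unconditional mean decision time `(a/v)·P_upper - w/v`.

Response coding: the upper boundary is "bird", the lower "dog".  Drift is
stimulus-signed (`+v` on bird-target trials, `-v` on dog-target trials),
so `v` measures accumulation toward the correct response and `z` is a
response bias toward "bird" — this keeps "bias > 0.5" interpretable as a
category preference.  The plain log-likelihood (`ddm_core.loglik`) scores
a table as-is; the stimulus-signed variant is opt-in and used by the
hierarchical fit whenever a `target` column is present.

The Euler–Maruyama simulator (default `dt = 0.1` ms) doubles as the data
generator and an independent Monte-Carlo oracle; its discretization bias
at this `dt` is below the 2 % tolerances used in the tests.

## Hierarchical estimation

Subject-level parameters are drawn from group-level Gaussians, one group
per condition for each family in the model's `varying` set.  The model
space is the power set of {v, a, t} (8 variants, numbered 1 = nothing
varies … 8 = all vary); `z` is shared across conditions.  Priors are
weakly informative: group means `v ~ N(2, 3²)`, `a ~ N(1.5, 0.75²)`
truncated above 0.3, `t ~ N(0.4, 0.2²)` truncated at 0, `logit(z) ~
N(0, 1)`; all group SDs half-normal(1).  Truncations keep the likelihood
defined; results at the simulated scales are insensitive to these choices.

The sampler is Metropolis-within-Gibbs:

* subject-level parameters: componentwise Gaussian random walks,
  vectorized across subjects (they are conditionally independent), with
  Robbins–Monro step-size adaptation toward a 0.44 acceptance rate during
  burn-in only;
* group means: exact conjugate draws (truncated normal where the prior is
  truncated);
* group SDs: independence Metropolis with the inverse-gamma conditional
  under a flat prior as proposal — the acceptance ratio then reduces to
  the half-normal factor `exp((σ²_cur - σ²_prop)/2)`, giving near-perfect
  mixing and avoiding the usual funnel pathology when the between-subject
  variance is small.

Each recorded draw advances the chain by 6 full sweeps (internal
thinning, chosen so the kept draws decorrelate enough for reliable
diagnostics); with 2 chains, 2,000 recorded draws and 500 burn-in, all
group-level split-R̂ values stay near 1.04 at the scales used here
(10 subjects × 100 trials/condition).  Two chains is the default because
R̂ requires at least two.  The WFPT series is evaluated by a compiled
(numba) kernel when available, with the pure-numpy evaluation as the
reference implementation; the two agree to the truncation tolerance and
the package runs identically (slower) without the compiler.

DIC is `D̄ + pD` with `pD = D̄ - D(θ̄)`; `D̄` is recomputed from the
supplied trial table for every kept draw (not read from the sampler
trace), and `θ̄` is the posterior mean of the subject-level parameters.
Condition effects are summarized by the directional posterior probability
`P(param_A > param_B)` over paired draws, flagged at < 0.05 / > 0.95 —
the operationalization of "less than 5 % posterior overlap".

## Behavioral filtering

Two tracks mirror the analysis they feed: descriptives use premature-
response removal (RT ≤ 0 from target onset) then a per-subject 3-SD trim
(sample SD, pooled across conditions); model fitting uses premature
removal then a per-subject 5 %-per-tail trim.  Tail trimming uses
linear-interpolation quantiles with strict-inequality removal; on
continuous data this removes exactly the nominal fraction.  Summaries
aggregate subject-first: each subject contributes one mean per
task × condition cell.

## EEG pipeline

Preprocessing is deterministic and ordered: channel selection → average
re-reference → zero-phase 4th-order Butterworth band-pass 0.5–40 Hz
(forward–backward, so the effective order doubles) → stimulus-locked
epochs on the half-open window [-200, 1000) ms (1,200 samples at 1 kHz) →
rejection of epochs exceeding ±120 μV (strict inequality).  Bad channels
are interpolated by inverse-distance weighting over the 4 nearest good
sensors — simpler than spherical splines and adequate at desk scale.
Independent-component artifact removal is out of scope; a hook accepts
externally cleaned epochs.

The discriminator slides a 60 ms window in 10 ms steps, window centers
-100…900 ms (101 windows).  Per window, channel features are the sample
means inside the window (an `all_samples` mode treating each sample as a
training exemplar exists behind a flag).  An L2-regularized logistic
regression (`λ = 1e-3`, Newton/IRLS) learns the spatial weighting; the
discriminant output `y = wᵀx + b` is oriented positive-mean for
no-distractor trials.  Performance is the ROC area (Az) of out-of-sample
`y` under leave-one-trial-out cross-validation.  LOO-CV AUC carries a
small pessimistic bias at chance (measured 0.483 over 20 null datasets,
101 windows) — worth knowing when reading "chance ≈ 0.5".  Significance
thresholds come from label permutations with full re-cross-validation;
a 10-fold CV mode exists for desk-scale permutation counts, and a
max-statistic variant returns a single global threshold controlling the
family-wise error over the strongly correlated windows (adjacent windows
share 50 of 60 ms).  Forward models `a = Xᵀy/(yᵀy)` map each component
back to channel space.

## Component windows and group statistics

Forward-model topographies of windows with persistent significant
discrimination are clustered by k-means (Euclidean, 10 seeded restarts)
for k = 2…6; k is chosen by mean silhouette.  Component windows are the
maximal contiguous runs of one cluster label.  Selection of the windows
entering clustering uses the family-wise (max-statistic) threshold plus a
minimum of three contiguous significant windows: with per-window
thresholds alone, correlated-window noise excursions at the component
edges create spurious clusters, and isolated false positives (expected at
α = 0.05 over 101 windows) form singleton clusters.

Group comparison of two Az traces (matched subjects) uses a percentile
bootstrap over subjects per window; the CI spans the 2.5–97.5 percentiles
and a window is significant when the CI excludes zero at the 2.5 % bound
in either direction.  Measured small-sample behavior on exchangeable null
data: per-window type-I error 0.108 at 10 subjects, 0.064 at 39 subjects
(nominal 0.05) — the known mild anti-conservatism of percentile
bootstraps, which shrinks with cohort size.  The cluster criterion is the
95th percentile of a max-cluster-size null obtained by shuffling temporal
sample order; because the per-window test depends only on that window's
own data, the shuffle relocates the observed per-window decisions without
changing them, so the null is computed by permuting the observed
significance mask — an exact, cheap reduction.  The criterion is floored
at 3 consecutive windows (30 ms).  Participant consistency is the
fraction of subjects whose mean effect over a cluster matches the group
sign; it is undefined (reported missing) when the group mean is exactly
zero.

## Synthetic EEG: what it does and does not emulate

Epochs are white (or AR(1)) noise per trial/channel with
condition-discriminative components added on distractor trials:
`amplitude · topography ⊗ h(t)` with `h` a raised-cosine bump on the
component window (190–370 ms "early", 520–630 ms "late" by default; AD
trials carry the early component and VD the late, configurable).  The
default desk-scale montage is 32 synthetic channels (Fibonacci lattice on
the upper hemisphere) at 250 Hz; 98/128 channels at 1,000 Hz are
reachable through configuration.  Not emulated: volume conduction from
real sources, eye/muscle artifacts, 1/f spectra, between-subject
topography variability, or any linkage between single-trial EEG amplitude
and the diffusion process.  Passing tests therefore demonstrate that the
pipeline recovers planted structure at realistic SNR and is calibrated
under its own null — not that real recordings would yield any particular
result.

## Problem sizes and numerical choices

Tests and the reproduction script run scaled-down problem sizes chosen to
exercise every stage meaningfully: decoder calibration uses 20 null
datasets of 100 trials × 32 channels; type-I calibration 100 datasets
with 200 permutations (10-fold CV mode); hierarchical fits use 10
subjects × 100 trials/condition (convergence) and 20 subjects × 150
trials/condition (model comparison) with 2 chains × 2,000 draws.  The
behavioral simulator uses `dt = 0.2` ms for cohort generation.  Ties in
peak-latency search break to the earlier window; k-means ties in
silhouette break to the smaller k; amplitude rejection and tail trimming
use strict inequalities; degenerate inputs (all-identical topographies,
zero discriminant output, single-chain diagnostics, subjects with fewer
than 2 trials) raise or warn explicitly rather than returning silent
defaults.

## Known limitations

* The sampler is a random-walk scheme; posteriors with strong
  subject-level correlations mix more slowly than gradient-based
  samplers would — adequate at the tested scales, but R̂ should be
  checked when pushing to many more conditions or parameters.
* The percentile bootstrap's small-n anti-conservatism is inherited from
  the method by design; sign-flip permutation is available via
  configuration where strict type-I control matters.
* Forward-model clustering assumes components express as quasi-stationary
  topographies within a window; drifting sources would blur the
  transition points.
* The EEG generator's noise is spatially white; spatially correlated
  noise would lower effective SNR for a fixed amplitude/noise ratio.
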