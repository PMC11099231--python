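# driftdecode

Evidence-accumulation analysis of distractor effects on categorical
decision-making: hierarchical drift-diffusion modeling (HDDM) of
choice/RT data and single-trial sliding-window EEG discrimination, with
forward-model topographies, temporal component clustering, and
cluster-based group bootstrap statistics.  A synthetic-data generator
emulating the study design (three conditions — no distractor ND,
auditory distractor AD, visual distractor VD — per task) makes every
stage testable end-to-end without access to recorded data.

The package is aimed at cognitive-neuroscience researchers who want a
reusable, tested implementation of this analysis style — or who want to
study its calibration (decoder chance level, permutation-threshold
type-I error, bootstrap coverage) on data with known ground truth.

## The models at the core

**Diffusion model.**  A decision variable starts at `w = z·a` between
absorbing boundaries 0 and `a`, accumulates evidence at drift rate `v`
(unit diffusion), and the response time adds a non-decision offset `t`.
The choice/RT likelihood is the Wiener first-passage-time (WFPT)
density, computed by a dual small-time/large-time series expansion.
Subject parameters are drawn from group-level Gaussians; eight model
variants let any subset of {v, a, t} vary by condition (model 1 = none,
…, model 8 = all).  Models are compared by DIC (lower is better; a
margin of 10 counts as decisive), convergence by the split Gelman–Rubin
R̂, and condition effects by directional posterior probabilities
`p_Bayes = P(θ_A > θ_B)`.

**Single-trial discrimination.**  For each 60 ms window sliding in
10 ms steps (centers −100…900 ms), an L2-regularized logistic
regression learns channel weights `w(τ)` whose projection
`y_i = wᵀx_i + b` separates distractor from no-distractor trials
(Eq. 1 style).  Performance is the ROC area Az of leave-one-trial-out
projections; significance thresholds come from label permutations; the
forward model `a(τ) = Xᵀy/(yᵀy)` (Eq. 2 style) maps each component to a
scalp topography.  Topographies are k-means-clustered over time
(silhouette-selected k) into temporal components, and group-level Az
differences are tested with a subject-level percentile bootstrap plus a
max-cluster-size permutation criterion (≥ 3 consecutive windows).

See `docs/methods.md` for assumptions, priors, numerical choices, and
what the synthetic generator does and does not emulate.

## Worked example

Six simulated subjects with a slower drift rate under auditory
distraction (`v`: ND 1.8, AD 1.1, VD 1.8), fitted with the
drift-varying model; then a planted early EEG component recovered by
the decoder:

```python
import numpy as np, pandas as pd
from driftdecode import (DDMParams, DesignSpec, ComponentSpec, ModelSpec,
                         make_trial_schedule, simulate_behavior, simulate_epochs,
                         fit_hierarchical, dic, gelman_rubin, loo_discriminant,
                         SlidingWindowConfig)
from driftdecode.decode import peak_latency
from driftdecode.hddm_fit import posterior_prob_greater

truth = {"ND": DDMParams(v=1.8, a=1.4, z=0.5, t=0.3),
         "AD": DDMParams(v=1.1, a=1.4, z=0.5, t=0.3),
         "VD": DDMParams(v=1.8, a=1.4, z=0.5, t=0.3)}
tables = []
for s in range(6):
    sched = make_trial_schedule(DesignSpec(), "visual", seed=100 + s)
    beh = simulate_behavior(sched, truth, seed=200 + s, dt=2e-4)
    beh["subject_id"] = f"S{s:02d}"
    tables.append(beh)
trials = pd.concat(tables, ignore_index=True)

fit = fit_hierarchical(trials, ModelSpec.from_number(2),
                       n_samples=1200, n_burn=400, seed=0)
for c in ("ND", "AD", "VD"):
    d = fit.draws[f"mu_v({c})"]
    print(f"mu_v({c}) = {d.mean():.2f} +- {d.std():.2f}")
p, sig = posterior_prob_greater(fit.draws["mu_v(AD)"].ravel(),
                                fit.draws["mu_v(ND)"].ravel())
print(f"p_Bayes(AD > ND) = {p:.3f}  significant={sig}")
rh = gelman_rubin(fit)
print("max group R-hat =", round(max(rh[k] for k in fit.group_parameters()), 3))
print("DIC(model 2) =", round(dic(fit, trials), 1))

rng = np.random.default_rng(0)
topo = rng.standard_normal(32)
early = ComponentSpec((190., 370.), topo, amplitude=2.0, noise_sd=1.0)
late = ComponentSpec((520., 630.), topo, amplitude=0.0, noise_sd=1.0)
sched = make_trial_schedule(DesignSpec(n_nd=60, n_ad=60, n_vd=1), "visual", seed=1)
sched = sched[sched["condition"].isin(["ND", "AD"])].reset_index(drop=True)
ep = simulate_epochs(sched, early, late, 250.0, seed=2)
labels = np.array([1 if l == "ND" else 0 for l in ep.labels])
res = loo_discriminant(ep, labels, SlidingWindowConfig())
print(f"peak Az = {res.az.max():.3f} at "
      f"{res.window_centers_ms[res.az.argmax()]:.0f} ms")
print(f"early-window peak latency = {peak_latency(res, (190., 370.)):.0f} ms")
```

Output:

```
mu_v(ND) = 1.88 +- 0.14
mu_v(AD) = 1.09 +- 0.08
mu_v(VD) = 1.83 +- 0.10
p_Bayes(AD > ND) = 0.000  significant=True
max group R-hat = 1.041
DIC(model 2) = 585.1
peak Az = 1.000 at 240 ms
early-window peak latency = 240 ms
```

The group drift rates recover the generative values; the directional
posterior probability flags the AD slowdown; R̂ below 1.1 indicates
converged chains.  The decoder finds near-perfect discrimination peaking
at 240 ms — inside the planted 190–370 ms window (the raised-cosine
component peaks at its window center, 280 ms, and the discriminator's
peak falls within sampling noise of it).

A command-line interface covers the same stages
(`driftdecode simulate | fit-ddm | decode | cluster | group | report`);
every stochastic stage takes an explicit `--seed` and reruns
byte-identically.

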