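"""Hierarchical Bayesian estimation of diffusion-model parameters.

Subject-level parameters are drawn from group-level Gaussian distributions
(one group per condition for each family in the model's ``varying`` set);
the relative starting point ``z`` is shared across conditions and sampled
on the logit scale.  The sampler is an adaptive Metropolis-within-Gibbs:
componentwise Gaussian random walks whose step sizes are tuned toward a
0.44 acceptance rate by Robbins-Monro adaptation during burn-in.  Subject
updates are vectorized across subjects (independent given the group
level).

Model space: the power set of {v, a, t} allowed to vary by condition,
numbered 1..8 (1 = nothing varies ... 8 = all three vary).  Models are
compared by DIC; convergence is checked with the split Gelman-Rubin
statistic; condition effects are summarized by directional posterior
probabilities.

Priors (weakly informative, configurable at the call site by editing
``GROUP_PRIORS``): group means v ~ N(2, 3^2); a ~ N(1.5, 0.75^2) truncated
above 0.3; t ~ N(0.4, 0.2^2) truncated at 0; logit(z) ~ N(0, 1); all group
SDs half-normal(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ddm_core import wfpt_logpdf

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "ModelComparison",
    "fit_hierarchical",
    "dic",
    "deviance_draws",
    "compare_models",
    "gelman_rubin",
    "posterior_prob_greater",
]

FAMILIES = ("v", "a", "t")

_MODEL_NUMBERS = {
    frozenset(): 1,
    frozenset({"v"}): 2,
    frozenset({"a"}): 3,
    frozenset({"t"}): 4,
    frozenset({"a", "t"}): 5,
    frozenset({"v", "a"}): 6,
    frozenset({"v", "t"}): 7,
    frozenset({"v", "a", "t"}): 8,
}
_NUMBER_TO_VARYING = {n: s for s, n in _MODEL_NUMBERS.items()}

# group-level prior hyperparameters: (mean, sd, lower truncation)
GROUP_PRIORS = {
    "v": (2.0, 3.0, -np.inf),
    "a": (1.5, 0.75, 0.3),
    "t": (0.4, 0.2, 0.0),
    "z": (0.0, 1.0, -np.inf),  # logit scale
}
_SUBJECT_LOWER = {"v": -np.inf, "a": 0.05, "t": 0.0, "z": -np.inf}


@dataclass(frozen=True)
class ModelSpec:
    """Which diffusion parameters may differ between conditions."""

    varying: frozenset = frozenset()
    include_z: bool = True

    def __post_init__(self) -> None:
        if not frozenset(self.varying) <= frozenset(FAMILIES):
            raise ValueError(f"varying must be a subset of {FAMILIES}")
        object.__setattr__(self, "varying", frozenset(self.varying))

    @classmethod
    def from_number(cls, n: int, include_z: bool = True) -> "ModelSpec":
        if n not in _NUMBER_TO_VARYING:
            raise ValueError(f"model number must be 1..8, got {n}")
        return cls(_NUMBER_TO_VARYING[n], include_z)

    @property
    def number(self) -> int:
        return _MODEL_NUMBERS[self.varying]


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws: each entry is [n_chains x n_kept]."""

    draws: dict
    n_burn: int
    seed: int
    model: ModelSpec
    subjects: list
    conditions: list

    def group_parameters(self) -> list:
        return [k for k in self.draws if k.startswith(("mu_", "sigma_"))]


@dataclass
class ModelComparison:
    dic: dict
    best_model: int
    margin: float
    significant: bool
    failures: dict = field(default_factory=dict)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _prepare(trials: pd.DataFrame, spec: ModelSpec):
    """Concatenated per-condition arrays plus subject bookkeeping."""
    subjects = sorted(trials["subject_id"].unique().tolist())
    order = [c for c in ("ND", "AD", "VD") if c in set(trials["condition"])]
    extra = [c for c in trials["condition"].unique() if c not in order]
    conditions = order + sorted(extra)
    if spec.varying and len(conditions) > 1:
        counts = trials.groupby(["subject_id", "condition"]).size().unstack(fill_value=0)
        for c in conditions:
            empty = counts.index[counts.get(c, pd.Series(0, index=counts.index)) == 0]
            if len(empty):
                raise ValueError(f"subject(s) {list(empty)} have no trials in condition {c}")
    sid_map = {s: i for i, s in enumerate(subjects)}
    has_target = "target" in trials.columns
    data = {}
    for ci, c in enumerate(conditions):
        sub = trials[trials["condition"] == c]
        rt = sub["rt_ms"].to_numpy(dtype=float) / 1000.0
        if np.any(rt <= 0):
            raise ValueError("all rt_ms must be positive; filter premature trials first")
        upper = sub["choice"].to_numpy() == "bird"
        if has_target:
            vsign = np.where(sub["target"].to_numpy() == "bird", 1.0, -1.0)
        else:
            vsign = np.ones(len(sub))
        sidx = sub["subject_id"].map(sid_map).to_numpy(dtype=int)
        data[ci] = (rt, upper, vsign, sidx)
    return subjects, conditions, data


class _State:
    """One chain's parameter state with cached per-(subject, condition) loglik."""

    def __init__(self, spec, subjects, conditions, data, rng):
        self.spec = spec
        self.n_subj = len(subjects)
        self.n_cond = len(conditions)
        self.data = data
        self.rng = rng
        ns = self.n_subj
        self.ngroups = {f: (self.n_cond if f in spec.varying else 1) for f in FAMILIES}
        min_rt = np.full(ns, np.inf)
        for rt, _, _, sidx in data.values():
            np.minimum.at(min_rt, sidx, rt)
        min_rt[~np.isfinite(min_rt)] = 0.5
        self.theta = {
            "v": 1.0 + 0.2 * rng.standard_normal((ns, self.ngroups["v"])),
            "a": 1.5 + 0.1 * rng.standard_normal((ns, self.ngroups["a"])),
            "t": np.clip(
                0.5 * min_rt[:, None] * np.ones((1, self.ngroups["t"]))
                + 0.02 * rng.standard_normal((ns, self.ngroups["t"])),
                1e-3,
                None,
            ),
        }
        self.zl = 0.1 * rng.standard_normal(ns) if spec.include_z else np.zeros(ns)
        self.mu = {f: self.theta[f].mean(axis=0) for f in FAMILIES}
        self.mu["a"] = np.maximum(self.mu["a"], 0.35)
        self.sig = {f: np.full(self.ngroups[f], 0.2) for f in FAMILIES}
        self.mu_zl, self.sig_zl = 0.0, 0.2
        # adaptive log step sizes for the subject-level random walks
        self.lstep = {
            ("subj", "v"): np.log(0.3) * np.ones(self.ngroups["v"]),
            ("subj", "a"): np.log(0.15) * np.ones(self.ngroups["a"]),
            ("subj", "t"): np.log(0.04) * np.ones(self.ngroups["t"]),
            ("subj", "z"): np.array([np.log(0.3)]),
        }
        self.ll = np.zeros((ns, self.n_cond))
        for ci in range(self.n_cond):
            self.ll[:, ci] = self._cond_loglik(ci)

    # -- likelihood helpers -------------------------------------------------
    def _group_of(self, f, ci):
        return ci if f in self.spec.varying else 0

    def _cond_loglik(self, ci, theta=None, zl=None):
        """Per-subject loglik for condition ci under (optionally proposed) params."""
        theta = theta if theta is not None else self.theta
        zl = zl if zl is not None else self.zl
        rt, upper, vsign, sidx = self.data[ci]
        v = theta["v"][sidx, self._group_of("v", ci)] * vsign
        a = theta["a"][sidx, self._group_of("a", ci)]
        t = theta["t"][sidx, self._group_of("t", ci)]
        z = _logistic(zl[sidx])
        logd = wfpt_logpdf(rt, upper, v, a, z, t)
        # -inf densities (rt below non-decision time) propagate to -inf sums
        return np.bincount(sidx, weights=logd, minlength=self.n_subj)

    # -- update blocks ------------------------------------------------------
    def _adapt(self, key, g, acc_rate, gamma):
        self.lstep[key][g] = np.clip(self.lstep[key][g] + gamma * (acc_rate - 0.44), -12, 3)

    def update_subject_family(self, f, g, gamma):
        """Vectorized across subjects: RW update of theta[f][:, g]."""
        conds = [ci for ci in range(self.n_cond) if self._group_of(f, ci) == g]
        cur = self.theta[f][:, g]
        step = np.exp(self.lstep[("subj", f)][g])
        prop = cur + step * self.rng.standard_normal(self.n_subj)
        ok = prop > _SUBJECT_LOWER[f]
        theta_prop = {k: (v if k != f else v.copy()) for k, v in self.theta.items()}
        theta_prop[f][:, g] = np.where(ok, prop, cur)
        new_ll = np.stack([self._cond_loglik(ci, theta=theta_prop) for ci in conds], axis=1)
        old_ll = self.ll[:, conds]
        mu, sig = self.mu[f][g], self.sig[f][g]
        dprior = ((cur - mu) ** 2 - (prop - mu) ** 2) / (2.0 * sig**2)
        logr = new_ll.sum(axis=1) - old_ll.sum(axis=1) + dprior
        acc = ok & (np.log(self.rng.random(self.n_subj)) < logr)
        if acc.any():
            self.theta[f][acc, g] = prop[acc]
            self.ll[np.ix_(acc, conds)] = new_ll[acc]
        if gamma is not None:
            self._adapt(("subj", f), g, acc.mean(), gamma)

    def update_subject_z(self, gamma):
        if not self.spec.include_z:
            return
        conds = list(range(self.n_cond))
        cur = self.zl
        step = np.exp(self.lstep[("subj", "z")][0])
        prop = cur + step * self.rng.standard_normal(self.n_subj)
        new_ll = np.stack([self._cond_loglik(ci, zl=prop) for ci in conds], axis=1)
        dprior = ((cur - self.mu_zl) ** 2 - (prop - self.mu_zl) ** 2) / (2.0 * self.sig_zl**2)
        logr = new_ll.sum(axis=1) - self.ll.sum(axis=1) + dprior
        acc = np.log(self.rng.random(self.n_subj)) < logr
        if acc.any():
            self.zl = np.where(acc, prop, cur)
            self.ll[acc] = new_ll[acc]
        if gamma is not None:
            self._adapt(("subj", "z"), 0, acc.mean(), gamma)

    def _draw_group_mean(self, th, sig, pm, ps, lower):
        """Gibbs draw of a group mean: conjugate normal, truncated below."""
        n = th.size
        var = 1.0 / (n / sig**2 + 1.0 / ps**2)
        mean = var * (th.sum() / sig**2 + pm / ps**2)
        sd = np.sqrt(var)
        if np.isneginf(lower):
            return mean + sd * self.rng.standard_normal()
        # inverse-CDF sampling of the truncated normal
        u = self.rng.random()
        lo_cdf = norm.cdf((lower - mean) / sd)
        return mean + sd * norm.ppf(lo_cdf + u * (1.0 - lo_cdf))

    def _draw_group_sd(self, th, mu, cur):
        """Independence-Metropolis draw of a group SD (half-normal(1) prior).

        Proposal: sigma^2 ~ InvGamma((n-1)/2, S/2), the conditional under a
        flat prior; the target/proposal ratio reduces to the half-normal
        factor, so the acceptance probability is exp((cur^2 - prop^2)/2).
        """
        n = th.size
        S = float(np.sum((th - mu) ** 2)) + 1e-12
        shape = (n - 1) / 2.0
        prop_var = S / 2.0 / self.rng.gamma(shape)
        if np.log(self.rng.random()) < (cur**2 - prop_var) / 2.0:
            return float(np.sqrt(prop_var))
        return cur

    def update_group(self):
        for f in FAMILIES:
            pm, ps, lower = GROUP_PRIORS[f]
            for g in range(self.ngroups[f]):
                th = self.theta[f][:, g]
                self.mu[f][g] = self._draw_group_mean(th, self.sig[f][g], pm, ps, lower)
                self.sig[f][g] = self._draw_group_sd(th, self.mu[f][g], self.sig[f][g])
        if self.spec.include_z:
            pm, ps, lower = GROUP_PRIORS["z"]
            self.mu_zl = self._draw_group_mean(self.zl, self.sig_zl, pm, ps, lower)
            self.sig_zl = self._draw_group_sd(self.zl, self.mu_zl, self.sig_zl)


def _param_names(spec, subjects, conditions):
    names = []
    for f in FAMILIES:
        groups = conditions if f in spec.varying else [None]
        for c in groups:
            tag = f"({c})" if c is not None else ""
            names.append(f"mu_{f}{tag}")
            names.append(f"sigma_{f}{tag}")
            for s in subjects:
                names.append(f"{f}_{s}{tag}")
    if spec.include_z:
        names += ["mu_z_logit", "sigma_z_logit"] + [f"z_{s}" for s in subjects]
    names.append("deviance")
    return names


def fit_hierarchical(
    trials: pd.DataFrame,
    spec: ModelSpec,
    n_samples: int = 5500,
    n_burn: int = 500,
    n_chains: int = 2,
    seed: int = 0,
    sweeps_per_draw: int = 6,
) -> PosteriorSamples:
    """Sample the joint posterior of the hierarchical diffusion model.

    ``n_samples`` is the total number of recorded MCMC iterations per
    chain; the first ``n_burn`` are discarded (and used for step-size
    adaptation).  Each recorded draw advances the chain by
    ``sweeps_per_draw`` full update sweeps (internal thinning that lowers
    autocorrelation of the kept draws).  Reruns with the same seed and data
    reproduce the draws exactly.
    """
    if n_samples <= n_burn:
        raise ValueError("n_samples must exceed n_burn")
    subjects, conditions, data = _prepare(trials, spec)
    if len(subjects) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    n_kept = n_samples - n_burn
    names = _param_names(spec, subjects, conditions)
    draws = {k: np.empty((n_chains, n_kept)) for k in names}

    for chain in range(n_chains):
        rng = np.random.default_rng([seed, chain])
        st = _State(spec, subjects, conditions, data, rng)
        kept = 0
        for it in range(n_samples):
            gamma = (it + 1.0) ** -0.6 if it < n_burn else None
            for _ in range(sweeps_per_draw):
                for f in FAMILIES:
                    for g in range(st.ngroups[f]):
                        st.update_subject_family(f, g, gamma)
                st.update_subject_z(gamma)
                st.update_group()
            if it >= n_burn:
                for f in FAMILIES:
                    groups = conditions if f in spec.varying else [None]
                    for gi, c in enumerate(groups):
                        tag = f"({c})" if c is not None else ""
                        draws[f"mu_{f}{tag}"][chain, kept] = st.mu[f][gi]
                        draws[f"sigma_{f}{tag}"][chain, kept] = st.sig[f][gi]
                        for si, s in enumerate(subjects):
                            draws[f"{f}_{s}{tag}"][chain, kept] = st.theta[f][si, gi]
                if spec.include_z:
                    draws["mu_z_logit"][chain, kept] = st.mu_zl
                    draws["sigma_z_logit"][chain, kept] = st.sig_zl
                    for si, s in enumerate(subjects):
                        draws[f"z_{s}"][chain, kept] = _logistic(st.zl[si])
                draws["deviance"][chain, kept] = -2.0 * st.ll.sum()
                kept += 1
    return PosteriorSamples(draws, n_burn, seed, spec, subjects, conditions)


def _loglik_at(samples: PosteriorSamples, trials: pd.DataFrame, point: dict) -> float:
    """Total data log-likelihood at a point estimate of subject parameters."""
    spec = samples.model
    subjects, conditions, data = _prepare(trials, spec)
    total = 0.0
    for ci, c in enumerate(conditions):
        rt, upper, vsign, sidx = data[ci]
        def val(f):
            tag = f"({c})" if f in spec.varying else ""
            return np.array([point[f"{f}_{s}{tag}"] for s in subjects])
        v = val("v")[sidx] * vsign
        a = val("a")[sidx]
        t = val("t")[sidx]
        if spec.include_z:
            z = np.array([point[f"z_{s}"] for s in subjects])[sidx]
        else:
            z = 0.5
        total += float(np.sum(wfpt_logpdf(rt, upper, v, a, z, t)))
    return total


def deviance_draws(samples: PosteriorSamples, trials: pd.DataFrame) -> np.ndarray:
    """Per-draw deviance ``-2 loglik`` recomputed from the trial table."""
    spec = samples.model
    subjects, conditions, data = _prepare(trials, spec)
    n_chains, n_kept = samples.draws["deviance"].shape
    dev = np.zeros(n_chains * n_kept)
    for ci, c in enumerate(conditions):
        rt, upper, vsign, sidx = data[ci]

        def fam(f):
            tag = f"({c})" if f in spec.varying else ""
            return np.stack([samples.draws[f"{f}_{s}{tag}"].ravel() for s in subjects])

        V, A, T = fam("v"), fam("a"), fam("t")
        if spec.include_z:
            Z = np.stack([samples.draws[f"z_{s}"].ravel() for s in subjects])
        else:
            Z = np.full_like(V, 0.5)
        for j in range(dev.size):
            ll = np.sum(
                wfpt_logpdf(rt, upper, V[sidx, j] * vsign, A[sidx, j], Z[sidx, j], T[sidx, j])
            )
            dev[j] += -2.0 * ll
    return dev.reshape(n_chains, n_kept)


def dic(samples: PosteriorSamples, trials: pd.DataFrame) -> float:
    """Deviance information criterion: ``DIC = Dbar + pD``.

    ``Dbar`` is the posterior-mean deviance, recomputed from ``trials`` for
    every kept draw; ``pD = Dbar - D(theta_bar)`` with the deviance
    evaluated at the posterior mean of the subject-level parameters.
    """
    dbar = float(deviance_draws(samples, trials).mean())
    point = {
        k: float(vals.mean())
        for k, vals in samples.draws.items()
        if not k.startswith(("mu_", "sigma_")) and k != "deviance"
    }
    d_at_mean = -2.0 * _loglik_at(samples, trials, point)
    return 2.0 * dbar - d_at_mean


def compare_models(
    trials: pd.DataFrame,
    n_samples: int = 5500,
    n_burn: int = 500,
    n_chains: int = 2,
    seed: int = 0,
    include_z: bool = True,
    model_numbers=range(1, 9),
) -> ModelComparison:
    """Fit every model variant and rank by DIC (margin >= 10 flags significance)."""
    dics, failures = {}, {}
    for n in model_numbers:
        spec = ModelSpec.from_number(n, include_z)
        try:
            fit = fit_hierarchical(trials, spec, n_samples, n_burn, n_chains, seed)
            dics[n] = dic(fit, trials)
        except Exception as exc:  # noqa: BLE001 - partial comparison is the contract
            failures[n] = str(exc)
    if not dics:
        raise RuntimeError("all model fits failed")
    best = min(dics, key=dics.get)
    others = [d for n, d in dics.items() if n != best]
    margin = (min(others) - dics[best]) if others else np.inf
    return ModelComparison(dics, best, float(margin), bool(margin >= 10.0), failures)


def gelman_rubin(samples: PosteriorSamples) -> dict:
    """Split-R-hat per parameter (between- vs within-chain variance)."""
    any_draw = next(iter(samples.draws.values()))
    if any_draw.shape[0] < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    out = {}
    for name, chains in samples.draws.items():
        if name == "deviance":
            continue
        half = chains.shape[1] // 2
        split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
        n = split.shape[1]
        W = split.var(axis=1, ddof=1).mean()
        if W == 0:
            out[name] = 1.0
            continue
        B_over_n = split.mean(axis=1).var(ddof=1)
        var_plus = (n - 1) / n * W + B_over_n
        out[name] = float(np.sqrt(var_plus / W))
    return out


def posterior_prob_greater(draws_a, draws_b, rng_seed: int = 0):
    """P(a > b) from posterior draws, with a <5% / >95% significance flag.

    Paired when the draw counts match (same MCMC iterations); otherwise all
    cross pairs are compared (subsampled above 10^7 pairs).
    """
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("draws must be non-empty")
    if a.size == b.size:
        p = float(np.mean(a > b))
    elif a.size * b.size <= 10_000_000:
        p = float(np.mean(a[:, None] > b[None, :]))
    else:
        rng = np.random.default_rng(rng_seed)
        m = 1_000_000
        p = float(np.mean(rng.choice(a, m) > rng.choice(b, m)))
    return p, (p < 0.05 or p > 0.95)
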