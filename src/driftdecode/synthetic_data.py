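"""Synthetic study-design generator.

Emulates the two-task categorical decision-making design: per task, a
no-distractor (ND) block followed by auditory-distractor (AD) and
visual-distractor (VD) blocks in randomized order (default counts
60/120/120).  Auditory targets sit in a six-sound sequence (250 ms sounds,
50 ms gaps, 1,750 ms total); behavioral RT/choice come from the diffusion
model in :mod:`driftdecode.ddm_core`; EEG epochs carry planted
condition-discriminative components (raised-cosine time course on a fixed
scalp topography) over white or AR(1) background noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm_core import DDMParams, simulate_ddm
from .eeg_preprocess import ContinuousEEG, EpochSet, default_montage

__all__ = [
    "DesignSpec",
    "ComponentSpec",
    "make_trial_schedule",
    "sequence_duration",
    "simulate_behavior",
    "simulate_epochs",
    "simulate_null_epochs",
    "make_continuous_recording",
]

CONDITIONS = ("ND", "AD", "VD")


@dataclass(frozen=True)
class DesignSpec:
    """Per-task trial counts and auditory-sequence timing."""

    n_nd: int = 60
    n_ad: int = 120
    n_vd: int = 120
    sound_dur_ms: float = 250.0
    gap_ms: float = 50.0
    n_positions: int = 6
    nd_first: bool = True

    def __post_init__(self) -> None:
        if min(self.n_nd, self.n_ad, self.n_vd) < 1:
            raise ValueError("every condition needs at least 1 trial")
        if not (self.sound_dur_ms > 0 and self.gap_ms >= 0 and self.n_positions >= 1):
            raise ValueError("invalid sequence timing")


@dataclass
class ComponentSpec:
    """A planted discriminative component plus the background-noise model.

    ``topography`` is normalized to unit Euclidean norm; ``amplitude`` is the
    component gain added on distractor trials (0 disables the component).
    """

    window_ms: tuple[float, float]
    topography: np.ndarray
    amplitude: float = 1.0
    noise_sd: float = 1.0
    noise_model: str = "white"
    ar1_coef: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.window_ms
        if not lo < hi:
            raise ValueError("component window start must precede end")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.noise_model not in ("white", "ar1"):
            raise ValueError("noise_model must be 'white' or 'ar1'")
        if not -1.0 < self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in (-1, 1)")
        topo = np.asarray(self.topography, dtype=float)
        nrm = np.linalg.norm(topo)
        if nrm == 0:
            raise ValueError("topography must be nonzero")
        self.topography = topo / nrm


def sequence_duration(design: DesignSpec) -> float:
    """Total auditory-sequence duration in ms (sounds plus silent gaps)."""
    return design.n_positions * design.sound_dur_ms + (design.n_positions - 1) * design.gap_ms


def make_trial_schedule(design: DesignSpec, task: str, seed: int) -> pd.DataFrame:
    """Blocked trial schedule without RT/choice.

    ND comes first when ``nd_first``; AD/VD block order is randomized by
    ``seed``.  Target category (dog/bird) and target position are balanced /
    uniform; congruency is balanced within distractor blocks and "none" for
    ND.  Auditory target onset is ``(position-1) * (sound + gap)``; visual
    onsets are 0.
    """
    if task not in ("visual", "auditory"):
        raise ValueError(f"task must be 'visual' or 'auditory', got {task!r}")
    rng = np.random.default_rng(seed)
    counts = {"ND": design.n_nd, "AD": design.n_ad, "VD": design.n_vd}
    distractor_order = ["AD", "VD"] if rng.random() < 0.5 else ["VD", "AD"]
    blocks = (["ND"] if design.nd_first else []) + distractor_order
    if not design.nd_first:
        blocks.insert(rng.integers(0, 3), "ND")

    rows = []
    for cond in blocks:
        n = counts[cond]
        targets = np.array(["dog", "bird"])[np.arange(n) % 2]
        rng.shuffle(targets)
        positions = rng.integers(1, design.n_positions + 1, size=n)
        if cond == "ND":
            congr = np.array(["none"] * n)
        else:
            congr = np.array(["congruent", "incongruent"])[np.arange(n) % 2]
            rng.shuffle(congr)
        for i in range(n):
            onset = (
                (positions[i] - 1) * (design.sound_dur_ms + design.gap_ms)
                if task == "auditory"
                else 0.0
            )
            rows.append(
                {
                    "subject_id": "S01",
                    "task": task,
                    "condition": cond,
                    "congruency": congr[i],
                    "target": targets[i],
                    "target_position": int(positions[i]),
                    "target_onset_ms": onset,
                }
            )
    return pd.DataFrame(rows)


def simulate_behavior(
    schedule: pd.DataFrame,
    params_by_condition: dict[str, DDMParams],
    seed: int,
    dt: float = 1e-4,
) -> pd.DataFrame:
    """Fill ``rt_ms``, ``choice`` and ``correct`` by diffusion simulation.

    Drift is stimulus-signed: ``+v`` toward the upper ("bird") boundary on
    bird-target trials, ``-v`` on dog-target trials, so ``v`` is the rate of
    evidence accumulation toward the correct response and ``z`` a response
    bias toward "bird".  RT is measured from target onset, as in the trial
    table convention.
    """
    missing = set(schedule["condition"].unique()) - set(params_by_condition)
    if missing:
        raise KeyError(f"no DDM parameters for condition(s): {sorted(missing)}")
    out = schedule.copy()
    out["rt_ms"] = np.nan
    out["choice"] = ""
    rng = np.random.default_rng(seed)
    for cond, p in params_by_condition.items():
        for tgt, sgn in (("bird", 1.0), ("dog", -1.0)):
            mask = (out["condition"] == cond) & (out["target"] == tgt)
            n = int(mask.sum())
            if n == 0:
                continue
            sub_seed = int(rng.integers(0, 2**31 - 1))
            p_eff = DDMParams(v=sgn * p.v, a=p.a, z=p.z, t=p.t)
            rt, up = simulate_ddm(p_eff, n, seed=sub_seed, dt=dt)
            out.loc[mask, "rt_ms"] = rt * 1000.0
            out.loc[mask, "choice"] = np.where(up, "bird", "dog")
    out["correct"] = out["choice"] == out["target"]
    return out


def _raised_cosine(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Smooth bump supported on ``window_ms``, peak 1 at the window center."""
    lo, hi = window_ms
    h = np.zeros_like(times_ms)
    inside = (times_ms >= lo) & (times_ms < hi)
    h[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (times_ms[inside] - lo) / (hi - lo)))
    return h


def _noise(rng, shape, spec: ComponentSpec) -> np.ndarray:
    if spec.noise_model == "white":
        return spec.noise_sd * rng.standard_normal(shape)
    # AR(1) over the time axis with stationary marginal sd = noise_sd
    innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar1_coef**2)
    eps = innov_sd * rng.standard_normal(shape)
    out = np.empty(shape)
    out[..., 0] = spec.noise_sd * rng.standard_normal(shape[:-1])
    for s in range(1, shape[-1]):
        out[..., s] = spec.ar1_coef * out[..., s - 1] + eps[..., s]
    return out


def simulate_epochs(
    schedule: pd.DataFrame,
    early: ComponentSpec,
    late: ComponentSpec,
    sfreq_hz: float = 250.0,
    epoch_window_ms: tuple[float, float] = (-200.0, 1000.0),
    seed: int = 0,
    assignment: dict[str, tuple[str, ...]] | None = None,
) -> EpochSet:
    """Epochs with planted components on distractor trials.

    Background noise (per the *early* spec's noise settings) on every trial;
    on distractor trials the assigned components are added as
    ``amplitude * topography (x) raised_cosine(t)``.  Default assignment
    mirrors the study's finding: AD trials carry the early component, VD
    trials the late one.  Labels are the schedule's conditions.
    """
    if assignment is None:
        assignment = {"AD": ("early",), "VD": ("late",)}
    comps = {"early": early, "late": late}
    tmin, tmax = epoch_window_ms
    for name, c in comps.items():
        if not (tmin <= c.window_ms[0] and c.window_ms[1] <= tmax):
            raise ValueError(f"{name} component window {c.window_ms} outside epoch window")
    if early.topography.shape != late.topography.shape:
        raise ValueError("early/late topographies must have equal length")
    n_channels = early.topography.size
    n_samples = int(round((tmax - tmin) * sfreq_hz / 1000.0))
    times_ms = tmin + np.arange(n_samples) * 1000.0 / sfreq_hz

    rng = np.random.default_rng(seed)
    n_trials = len(schedule)
    data = _noise(rng, (n_trials, n_channels, n_samples), early)

    conds = schedule["condition"].to_numpy()
    for cond, names in assignment.items():
        mask = conds == cond
        if not mask.any():
            continue
        for name in names:
            c = comps[name]
            if c.amplitude == 0:
                continue
            bump = c.amplitude * np.outer(c.topography, _raised_cosine(times_ms, c.window_ms))
            data[mask] += bump
    ch_names, _ = default_montage(n_channels)
    return EpochSet(data, times_ms, list(conds), sfreq_hz, ch_names)


def simulate_null_epochs(
    n_trials: int,
    n_channels: int,
    sfreq_hz: float,
    seed: int,
    noise_sd: float = 1.0,
    epoch_window_ms: tuple[float, float] = (-200.0, 1000.0),
) -> EpochSet:
    """Pure-noise epochs with balanced ND/AD labels (no planted signal)."""
    design = DesignSpec(n_nd=n_trials - n_trials // 2, n_ad=max(n_trials // 2, 1), n_vd=1)
    sched = make_trial_schedule(design, "visual", seed=seed)
    sched = sched[sched["condition"].isin(["ND", "AD"])].reset_index(drop=True)
    topo = np.zeros(n_channels)
    topo[0] = 1.0
    comp = lambda w: ComponentSpec(w, topo, amplitude=0.0, noise_sd=noise_sd)  # noqa: E731
    return simulate_epochs(
        sched, comp((190.0, 370.0)), comp((520.0, 630.0)), sfreq_hz, epoch_window_ms, seed=seed
    )


def make_continuous_recording(
    n_events: int,
    sfreq_hz: float,
    duration_s: float,
    seed: int,
    n_channels: int = 8,
    noise_sd: float = 1.0,
):
    """Noise recording with evenly spaced event markers.

    Events are placed in ``[0.5 s, duration - 1.5 s]`` so every event leaves
    room for a [-200, 1000) ms epoch.  Returns ``(ContinuousEEG, events)``.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    usable = duration_s - 2.0
    if n_events > 0 and usable <= 0:
        raise ValueError(f"duration {duration_s} s too short for {n_events} events")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sfreq_hz))
    names, pos = default_montage(n_channels)
    eeg = ContinuousEEG(noise_sd * rng.standard_normal((n_channels, n_samples)), sfreq_hz, names, pos)
    if n_events == 0:
        return eeg, np.array([], dtype=int)
    t_ev = 0.5 + usable * (np.arange(n_events) + 0.5) / n_events
    events = np.round(t_ev * sfreq_hz).astype(int)
    return eeg, events
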