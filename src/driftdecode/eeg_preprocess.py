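"""EEG containers and deterministic preprocessing.

Pipeline order (fixed): channel selection -> average re-reference ->
zero-phase Butterworth band-pass -> stimulus-locked epoching -> amplitude
rejection.  Bad-channel interpolation operates on continuous data.  All
amplitudes are in microvolts; time stamps in milliseconds.  Epoch windows
are half-open ``[tmin, tmax)`` so 1,200 ms at 1 kHz is exactly 1,200
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "ContinuousEEG",
    "EpochSet",
    "default_montage",
    "select_channels",
    "rereference_average",
    "bandpass_butterworth",
    "epoch",
    "reject_amplitude",
    "interpolate_bad_channels",
]


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording: ``data`` is [n_channels x n_samples]."""

    data: np.ndarray
    sfreq_hz: float
    channel_names: list[str]
    positions: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be 2-D [channels x samples]")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channel_names)} channel names"
            )
        if not self.sfreq_hz > 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class EpochSet:
    """Stimulus-locked epochs: ``data`` is [n_trials x n_channels x n_samples]."""

    data: np.ndarray
    times_ms: np.ndarray
    labels: list[str]
    sfreq_hz: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D [trials x channels x samples]")
        n_tr, n_ch, n_sm = self.data.shape
        if n_tr == 0:
            raise ValueError("empty epoch set")
        if len(self.labels) != n_tr:
            raise ValueError(f"{len(self.labels)} labels for {n_tr} trials")
        if len(self.channel_names) != n_ch:
            raise ValueError(f"{len(self.channel_names)} names for {n_ch} channels")
        if self.times_ms.size != n_sm:
            raise ValueError("times_ms length must equal n_samples")
        steps = np.diff(self.times_ms)
        if self.times_ms.size > 1 and not np.allclose(steps, 1000.0 / self.sfreq_hz):
            raise ValueError("times_ms must increase uniformly at 1000/sfreq_hz")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def default_montage(n_channels: int):
    """Synthetic spherical montage: names and unit-sphere positions.

    Channels are spread on the upper hemisphere with a Fibonacci lattice —
    a stand-in head layout for simulation and interpolation, not a real
    electrode net geometry.
    """
    names = [f"E{i + 1:03d}" for i in range(n_channels)]
    golden = np.pi * (3.0 - np.sqrt(5.0))
    pos = {}
    for i in range(n_channels):
        zc = 0.05 + 0.95 * (i + 0.5) / n_channels  # upper hemisphere
        r = np.sqrt(1.0 - zc**2)
        th = golden * i
        pos[names[i]] = np.array([r * np.cos(th), r * np.sin(th), zc])
    return names, pos


def select_channels(eeg: ContinuousEEG, include: list[str]) -> ContinuousEEG:
    """Restrict to the named channels, in the order given."""
    unknown = [c for c in include if c not in eeg.channel_names]
    if unknown:
        raise KeyError(f"unknown channel(s): {unknown}")
    idx = [eeg.channel_names.index(c) for c in include]
    pos = None
    if eeg.positions is not None:
        pos = {c: eeg.positions[c] for c in include if c in eeg.positions}
    return ContinuousEEG(eeg.data[idx], eeg.sfreq_hz, list(include), pos)


def rereference_average(eeg: ContinuousEEG) -> ContinuousEEG:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if eeg.data.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return replace(eeg, data=data)


def bandpass_butterworth(
    eeg: ContinuousEEG, low_hz: float = 0.5, high_hz: float = 40.0, order: int = 4
) -> ContinuousEEG:
    """Zero-phase (forward-backward) Butterworth band-pass.

    The filter is applied with ``sosfiltfilt``, so the effective magnitude
    response is the squared ``order``-th-order response and the phase is
    zero.
    """
    nyq = eeg.sfreq_hz / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=eeg.sfreq_hz, output="sos")
    data = signal.sosfiltfilt(sos, eeg.data, axis=1)
    return replace(eeg, data=data)


def epoch(
    eeg: ContinuousEEG,
    events: np.ndarray,
    tmin_ms: float = -200.0,
    tmax_ms: float = 1000.0,
    labels: list[str] | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs spanning ``[tmin_ms, tmax_ms)`` per event.

    Events without full margins inside the recording are skipped with a
    warning.  ``labels`` (one per event) follow their events; skipped events
    drop their label.
    """
    events = np.asarray(events, dtype=int)
    n0 = int(round(tmin_ms * eeg.sfreq_hz / 1000.0))
    n1 = int(round(tmax_ms * eeg.sfreq_hz / 1000.0))
    if n1 <= n0:
        raise ValueError("tmax_ms must exceed tmin_ms")
    n_samples = eeg.data.shape[1]
    keep, chunks = [], []
    for j, ev in enumerate(events):
        lo, hi = ev + n0, ev + n1
        if lo < 0 or hi > n_samples:
            warnings.warn(f"event {j} at sample {ev} lacks epoch margins; skipped")
            continue
        keep.append(j)
        chunks.append(eeg.data[:, lo:hi])
    if not chunks:
        raise ValueError("no valid events to epoch")
    data = np.stack(chunks, axis=0)
    times_ms = (np.arange(n0, n1) * 1000.0) / eeg.sfreq_hz
    if labels is None:
        lab = ["" for _ in keep]
    else:
        lab = [labels[j] for j in keep]
    return EpochSet(data, times_ms, lab, eeg.sfreq_hz, list(eeg.channel_names))


def reject_amplitude(epochs: EpochSet, limit_uv: float = 120.0):
    """Drop epochs whose absolute amplitude strictly exceeds ``limit_uv``.

    Returns ``(clean_epochs, dropped_indices)``.
    """
    if not limit_uv > 0:
        raise ValueError("limit_uv must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    bad = np.where(peak > limit_uv)[0]
    if bad.size == 0:
        return epochs, []
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad)
    if keep.size == 0:
        raise ValueError("amplitude rejection removed every epoch")
    clean = EpochSet(
        epochs.data[keep],
        epochs.times_ms,
        [epochs.labels[i] for i in keep],
        epochs.sfreq_hz,
        list(epochs.channel_names),
    )
    return clean, bad.tolist()


def interpolate_bad_channels(
    eeg: ContinuousEEG,
    bad: list[str],
    positions: dict[str, np.ndarray] | None = None,
    k: int = 4,
) -> ContinuousEEG:
    """Replace bad channels by an inverse-distance-weighted neighbor mean.

    Each bad channel becomes the 1/d-weighted average of its ``k`` nearest
    good channels (3-D sensor positions).  More than 5 % bad channels
    triggers a warning, mirroring common per-participant quality limits.
    """
    if not bad:
        return eeg
    positions = positions if positions is not None else eeg.positions
    if positions is None:
        raise ValueError("channel positions are required for interpolation")
    unknown = [c for c in bad if c not in eeg.channel_names]
    if unknown:
        raise KeyError(f"unknown bad channel(s): {unknown}")
    good = [c for c in eeg.channel_names if c not in set(bad)]
    if not good:
        raise ValueError("cannot interpolate: all channels marked bad")
    if len(bad) / len(eeg.channel_names) > 0.05:
        warnings.warn(
            f"{len(bad)}/{len(eeg.channel_names)} bad channels exceeds the 5% guideline"
        )
    data = eeg.data.copy()
    good_idx = np.array([eeg.channel_names.index(c) for c in good])
    good_pos = np.stack([np.asarray(positions[c], dtype=float) for c in good])
    for c in bad:
        ci = eeg.channel_names.index(c)
        d = np.linalg.norm(good_pos - np.asarray(positions[c], dtype=float), axis=1)
        order = np.argsort(d)[: min(k, len(good))]
        dd = np.maximum(d[order], 1e-12)
        wts = (1.0 / dd) / np.sum(1.0 / dd)
        data[ci] = wts @ eeg.data[good_idx[order]]
    return replace(eeg, data=data)
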