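"""Group-level statistics on decoder outputs.

Temporal clustering of forward-model topographies identifies component
windows (k-means over window topographies, k chosen by mean silhouette);
a percentile bootstrap over subjects compares Az traces between two
comparisons window by window; a max-cluster-size permutation null converts
per-window significance into contiguous temporal clusters (minimum length
floored at 3 consecutive windows); participant consistency reports the
fraction of subjects whose effect matches the group direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterReport",
    "GroupDiffResult",
    "cluster_topographies",
    "bootstrap_az_difference",
    "max_cluster_null",
    "find_clusters",
    "participant_consistency",
    "group_compare",
]


@dataclass
class ClusterReport:
    k_selected: int
    labels: np.ndarray                       # cluster label per window
    component_windows: list[tuple[int, int]]  # inclusive index spans per run
    component_windows_ms: list[tuple[float, float]] | None
    transition_points_ms: list[float]
    silhouette_by_k: dict[int, float]


@dataclass
class GroupDiffResult:
    mean_diff: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sig_mask: np.ndarray
    clusters: list[tuple[int, int]] = field(default_factory=list)
    min_cluster_len: int = 3
    consistency: float | None = None
    consistency_by_cluster: list[float | None] = field(default_factory=list)


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of identical values, as inclusive (start, end) spans."""
    spans = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            spans.append((start, i - 1))
            start = i
    return spans


def cluster_topographies(
    forward_models: np.ndarray,
    k_range=range(2, 7),
    seed: int = 0,
    window_centers_ms: np.ndarray | None = None,
    n_restarts: int = 10,
) -> ClusterReport:
    """k-means over window topographies with silhouette-selected k.

    ``forward_models`` is [n_windows x n_channels]; rows are clustered with
    Euclidean distance on the raw vectors.  Component windows are the
    maximal contiguous runs of a common cluster label; transition points
    are the run boundaries (midpoint between adjacent window centers when
    centers are given).
    """
    A = np.asarray(forward_models, dtype=float)
    k_range = list(k_range)
    if A.shape[0] < max(k_range) + 1:
        raise ValueError(f"need at least {max(k_range) + 1} windows for k up to {max(k_range)}")
    if np.allclose(A, A[0]):
        raise ValueError("no cluster structure: all topographies identical")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(A)
        labels_by_k[k] = lab
        sil[k] = float(silhouette_score(A, lab)) if len(np.unique(lab)) > 1 else -1.0
    k_sel = max(sil, key=lambda k: (sil[k], -k))
    lab = labels_by_k[k_sel]
    spans = _runs(lab)
    spans_ms = None
    transitions = []
    if window_centers_ms is not None:
        c = np.asarray(window_centers_ms, dtype=float)
        spans_ms = [(float(c[s]), float(c[e])) for s, e in spans]
        transitions = [float((c[e] + c[e + 1]) / 2.0) for _, e in spans[:-1]]
    return ClusterReport(k_sel, lab, spans, spans_ms, transitions, sil)


def bootstrap_az_difference(
    az_a: np.ndarray,
    az_b: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> GroupDiffResult:
    """Percentile bootstrap of the paired group-mean Az difference per window.

    ``az_a`` and ``az_b`` are [n_subjects x n_windows] with matched subject
    rows.  Subjects are resampled with replacement; the CI spans the
    ``alpha/2`` and ``1 - alpha/2`` percentiles of the bootstrap mean
    difference.  A window is significant when the CI excludes zero at the
    2.5 % bound in either direction.
    """
    A, B = np.asarray(az_a, dtype=float), np.asarray(az_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    n_subj = A.shape[0]
    if n_subj < 5:
        raise ValueError("need at least 5 subjects")
    diff = A - B
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    boot_means = diff[idx].mean(axis=1)  # (n_boot, n_windows)
    lo, hi = np.quantile(boot_means, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    mean_diff = diff.mean(axis=0)
    sig = (lo > 0.0) | (hi < 0.0)
    return GroupDiffResult(mean_diff, lo, hi, sig)


def find_clusters(sig_mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= ``min_len`` (inclusive index spans)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    mask = np.asarray(sig_mask, dtype=bool)
    return [
        (s, e) for s, e in _runs(mask) if mask[s] and (e - s + 1) >= min_len
    ]


def max_cluster_null(
    az_a: np.ndarray,
    az_b: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
) -> int:
    """Minimum cluster length from a max-cluster-size permutation null.

    Temporal order is shuffled without replacement while each window keeps
    its full cross-subject paired-difference data; since the per-window
    bootstrap test depends only on that window's data, shuffling relocates
    the observed per-window significance decisions without changing them.
    The null therefore permutes the observed significance mask and records
    the largest run of consecutive significant windows per permutation.
    Returns the ``1 - alpha_cluster`` percentile of that null, floored at 3
    consecutive windows.
    """
    base = bootstrap_az_difference(az_a, az_b, n_boot=n_boot, seed=seed)
    mask = base.sig_mask
    rng = np.random.default_rng(seed)
    max_sizes = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        perm = rng.permutation(mask)
        runs = find_clusters(perm, 1)
        max_sizes[r] = max((e - s + 1 for s, e in runs), default=0)
    crit = int(np.ceil(np.quantile(max_sizes, 1.0 - alpha_cluster)))
    return max(crit, 3)


def participant_consistency(
    diff_per_subject: np.ndarray, cluster: tuple[int, int]
) -> float | None:
    """Fraction of subjects whose mean cluster effect matches the group sign.

    Returns None (undefined) when the group mean over the cluster is zero.
    """
    D = np.asarray(diff_per_subject, dtype=float)
    s, e = cluster
    if not (0 <= s <= e < D.shape[1]):
        raise ValueError(f"cluster {cluster} outside the window grid")
    subj_means = D[:, s : e + 1].mean(axis=1)
    group = subj_means.mean()
    if group == 0.0:
        return None
    return float(np.mean(np.sign(subj_means) == np.sign(group)))


def group_compare(
    az_a: np.ndarray,
    az_b: np.ndarray,
    n_boot: int = 1000,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> GroupDiffResult:
    """Full group comparison: bootstrap CIs, cluster criterion, consistency."""
    res = bootstrap_az_difference(az_a, az_b, n_boot=n_boot, alpha=alpha, seed=seed)
    res.min_cluster_len = max_cluster_null(
        az_a, az_b, n_perm=n_perm, seed=seed + 1, n_boot=n_boot
    )
    res.clusters = find_clusters(res.sig_mask, res.min_cluster_len)
    # after cluster filtering, significance holds exactly on cluster members
    refined = np.zeros_like(res.sig_mask)
    for s, e in res.clusters:
        refined[s : e + 1] = True
    res.sig_mask = refined
    diff = np.asarray(az_a, dtype=float) - np.asarray(az_b, dtype=float)
    res.consistency_by_cluster = [participant_consistency(diff, c) for c in res.clusters]
    if res.clusters:
        largest = max(res.clusters, key=lambda c: c[1] - c[0])
        res.consistency = participant_consistency(diff, largest)
    return res
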