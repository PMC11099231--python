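"""Behavioral trial filtering and per-condition summaries.

Two filtering tracks feed different downstream analyses:

* descriptives: remove premature responses, then trials beyond 3 sample
  standard deviations of each participant's mean RT;
* diffusion-model fitting: remove premature responses, then the 5 % tails
  of each participant's RT distribution.

Filters only ever drop rows; each returns ``(table, report)`` with
per-subject removal counts.  Tail trimming uses linear-interpolation
quantiles with strict-inequality removal (``rt < q_low`` or
``rt > q_high``); the convention is recorded in the report.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "filter_premature",
    "trim_rt_sd",
    "trim_rt_tails",
    "condition_summaries",
]


def filter_premature(trials: pd.DataFrame):
    """Drop trials answered at or before target onset (``rt_ms <= 0``)."""
    keep = trials["rt_ms"].to_numpy(dtype=float) > 0
    report = {
        "rule": "premature (rt_ms <= 0)",
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    return trials.loc[keep].reset_index(drop=True), report


def trim_rt_sd(trials: pd.DataFrame, k: float = 3.0):
    """Per-subject trim of trials with ``|rt - mean| > k * sd``.

    Sample (n-1 denominator) standard deviation, pooled across conditions
    within each subject.  Subjects with fewer than 2 trials pass through
    unfiltered with a warning.
    """
    keep = np.ones(len(trials), dtype=bool)
    per_subject: dict[str, int] = {}
    for sid, grp in trials.groupby("subject_id", sort=False):
        rt = grp["rt_ms"].to_numpy(dtype=float)
        if rt.size < 2:
            warnings.warn(f"subject {sid}: fewer than 2 trials, SD trim skipped")
            per_subject[str(sid)] = 0
            continue
        mu, sd = rt.mean(), rt.std(ddof=1)
        bad = np.abs(rt - mu) > k * sd
        keep[grp.index[bad]] = False
        per_subject[str(sid)] = int(bad.sum())
    report = {"rule": f"|rt - mean| > {k} sd", "removed_by_subject": per_subject,
              "n_removed": int((~keep).sum())}
    return trials.loc[keep].reset_index(drop=True), report


def trim_rt_tails(trials: pd.DataFrame, tail: float = 0.05):
    """Per-subject removal of RTs strictly outside the central quantile band.

    Removes trials with ``rt < Q(tail)`` or ``rt > Q(1 - tail)`` of that
    subject's RT distribution (linear-interpolation quantiles).
    """
    if not 0.0 <= tail < 0.5:
        raise ValueError(f"tail must lie in [0, 0.5), got {tail}")
    keep = np.ones(len(trials), dtype=bool)
    per_subject: dict[str, int] = {}
    for sid, grp in trials.groupby("subject_id", sort=False):
        rt = grp["rt_ms"].to_numpy(dtype=float)
        q_lo, q_hi = np.quantile(rt, [tail, 1.0 - tail])
        bad = (rt < q_lo) | (rt > q_hi)
        keep[grp.index[bad]] = False
        per_subject[str(sid)] = int(bad.sum())
    report = {
        "rule": f"rt outside [{tail}, {1 - tail}] quantiles",
        "quantile_convention": "linear interpolation; strict-inequality removal",
        "removed_by_subject": per_subject,
        "n_removed": int((~keep).sum()),
    }
    return trials.loc[keep].reset_index(drop=True), report


def condition_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of accuracy and RT per task x condition.

    Subject-first aggregation: each subject contributes one mean per cell;
    the table reports the mean and sample SD of those subject means.  Empty
    cells appear as NaN rather than raising.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    subj = (
        trials.assign(correct=trials["correct"].astype(float))
        .groupby(["task", "condition", "subject_id"], sort=False)
        .agg(acc=("correct", "mean"), rt=("rt_ms", "mean"))
        .reset_index()
    )
    out = (
        subj.groupby(["task", "condition"], sort=False)
        .agg(
            n_subjects=("subject_id", "nunique"),
            acc_mean=("acc", "mean"),
            acc_sd=("acc", lambda x: x.std(ddof=1)),
            rt_mean=("rt", "mean"),
            rt_sd=("rt", lambda x: x.std(ddof=1)),
        )
        .reset_index()
    )
    return out
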