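"""Shared fixtures: small synthetic cohorts and a loader for the
acceptance-script runners (so the tests exercise exactly the code the
reproduction script runs)."""

from __future__ import annotations

import importlib.util
import sys
from pathlib import Path

import pandas as pd
import pytest

from driftdecode.ddm_core import DDMParams
from driftdecode.synthetic_data import DesignSpec, make_trial_schedule, simulate_behavior

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def acceptance():
    """The scripts/acceptance.py module, imported from the repo tree."""
    spec = importlib.util.spec_from_file_location(
        "acceptance_script", REPO_ROOT / "scripts" / "acceptance.py"
    )
    mod = importlib.util.module_from_spec(spec)
    sys.modules["acceptance_script"] = mod
    spec.loader.exec_module(mod)
    return mod


def make_cohort(n_subjects, n_per_cond, drifts=(1.5, 1.5, 1.5), seed=0, a=1.4, t=0.3):
    """Small multi-subject behavioral dataset from known DDM parameters."""
    truth = {c: DDMParams(v=v, a=a, z=0.5, t=t) for c, v in zip(("ND", "AD", "VD"), drifts)}
    tables = []
    for s in range(n_subjects):
        design = DesignSpec(n_nd=n_per_cond, n_ad=n_per_cond, n_vd=n_per_cond)
        sched = make_trial_schedule(design, "visual", seed=seed * 100 + s)
        beh = simulate_behavior(sched, truth, seed=seed * 100 + 50 + s, dt=2e-4)
        beh["subject_id"] = f"S{s:02d}"
        tables.append(beh)
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(n_subjects=3, n_per_cond=30, seed=7)


@pytest.fixture()
def simple_trials():
    """Hand-written trial table for filter tests."""
    return pd.DataFrame(
        {
            "subject_id": ["S01"] * 5,
            "task": ["visual"] * 5,
            "condition": ["ND", "ND", "AD", "AD", "VD"],
            "congruency": ["none", "none", "congruent", "incongruent", "congruent"],
            "target_onset_ms": [0.0] * 5,
            "rt_ms": [650.0, 700.0, 720.0, 680.0, 800.0],
            "choice": ["dog", "bird", "dog", "dog", "bird"],
            "correct": [True, True, False, True, True],
        }
    )
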