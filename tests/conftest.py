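"""Shared fixtures: small deterministic synthetic cohorts and builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ogttmet.config import SimConfig
from ogttmet.data import ROLE_BLANK, ROLE_QC, ROLE_STUDY, TimeCourseDataset
from ogttmet.sim import generate_blank_qc, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject, 40-metabolite cohort with planted effects, no missingness."""
    cfg = SimConfig(
        n_per_group=10,
        n_metabolites=40,
        n_affected=6,
        enriched_class_size=6,
        n_classes=5,
        n_high_rsd=2,
        n_blank_artifacts=2,
        missing_rate=0.0,
        seed=42,
    )
    dataset, truth = generate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def qc_cohort(small_cohort):
    """The small cohort with QC replicates and blank samples appended."""
    cfg, dataset, truth = small_cohort
    return cfg, generate_blank_qc(cfg, dataset), truth


def make_tiny_dataset(
    study_values: dict[str, list[float]],
    qc_values: dict[str, list[float]] | None = None,
    blank_values: dict[str, list[float]] | None = None,
    timepoints=(0, 15, 30, 60, 120),
) -> TimeCourseDataset:
    """Build a minimal dataset from explicit per-metabolite value lists.

    ``study_values[met]`` is a flat list interpreted as consecutive subjects'
    trajectories over ``timepoints`` (length must be a multiple of the grid).
    Subjects alternate between the almond and cracker arms.
    """
    mets = list(study_values)
    n_vals = len(next(iter(study_values.values())))
    n_t = len(timepoints)
    assert n_vals % n_t == 0
    n_sub = n_vals // n_t
    ids, rows = [], []
    for s in range(n_sub):
        grp = "almond" if s % 2 == 0 else "cracker"
        for t in timepoints:
            ids.append(f"s{s}_t{t}")
            rows.append((f"s{s}", grp, ROLE_STUDY, float(t)))
    data = {m: list(v) for m, v in study_values.items()}
    if qc_values:
        for k in range(len(next(iter(qc_values.values())))):
            ids.append(f"qc{k}")
            rows.append((None, None, ROLE_QC, np.nan))
        for m in mets:
            data[m] = data[m] + list(qc_values[m])
    if blank_values:
        for k in range(len(next(iter(blank_values.values())))):
            ids.append(f"blank{k}")
            rows.append((None, None, ROLE_BLANK, np.nan))
        for m in mets:
            data[m] = data[m] + list(blank_values[m])
    samples = pd.DataFrame(
        rows,
        index=pd.Index(ids, name="sample_id"),
        columns=["subject_id", "group", "role", "timepoint_min"],
    )
    intensities = pd.DataFrame(data, index=samples.index)
    return TimeCourseDataset(samples, intensities)
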