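"""Exclusion filters, imputation, and transformations.

Mirrors the standard untargeted-metabolomics cleanup for oGTT serum data:
metabolites whose QC-replicate relative standard deviation exceeds 50% are
excluded; metabolites indistinguishable from blanks (two-sample Wilcoxon
p > 0.05) or with median sample/blank ratio below 1 are excluded; remaining
missing values are imputed by iterative chained regression; analysis
matrices are log10-transformed and autoscaled. Sample SD (n-1 denominator)
is used throughout.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ROLE_BLANK, ROLE_QC, ROLE_STUDY, TimeCourseDataset


@dataclasses.dataclass
class FilterReport:
    """Outcome of one exclusion filter over all metabolites.

    ``table`` has one row per (metabolite, statistic) with columns
    metabolite, filter, statistic, value, removed — serializable as TSV for
    auditing. ``removed`` and ``retained`` partition the input metabolites.
    """

    filter_name: str
    table: pd.DataFrame
    removed: list[str]
    retained: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.removed) & set(self.retained)
        if overlap:
            raise ValueError(f"metabolite in both removed and retained: {overlap}")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def filter_qc_rsd(dataset: TimeCourseDataset, threshold: float = 0.5) -> FilterReport:
    """Flag metabolites whose QC-replicate RSD (SD/mean) exceeds ``threshold``.

    Metabolites with zero or undefined QC mean are treated as failing. Raises
    if the dataset carries fewer than two QC samples — skip the filter
    explicitly in that case.
    """
    qc = dataset.matrix(ROLE_QC)
    if len(qc) < 2:
        raise ValueError(
            "QC-RSD filter needs >= 2 QC-role samples; none/too few present "
            "- skip this filter explicitly if the dataset has no QC replicates"
        )
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    removed_mask = (mean <= 0) | ~np.isfinite(rsd) | (rsd > threshold)
    table = pd.DataFrame(
        {
            "metabolite": qc.columns,
            "filter": "qc_rsd",
            "statistic": "rsd",
            "value": rsd.to_numpy(),
            "removed": removed_mask.to_numpy(),
        }
    )
    removed = list(qc.columns[removed_mask])
    retained = list(qc.columns[~removed_mask])
    return FilterReport("qc_rsd", table, removed, retained)


def filter_blank(dataset: TimeCourseDataset, alpha: float = 0.05) -> FilterReport:
    """Flag metabolites indistinguishable from (or below) blanks.

    A metabolite is removed iff the two-sample Wilcoxon rank-sum test of
    study vs blank intensities has p > ``alpha`` OR the median study/blank
    ratio is below 1 (either criterion excludes). Exact enumeration is used
    at small per-side n without ties, the tie-corrected normal approximation
    otherwise.
    """
    blanks = dataset.matrix(ROLE_BLANK)
    if len(blanks) < 3:
        raise ValueError(
            "blank filter needs >= 3 blank-role samples - skip explicitly otherwise"
        )
    study = dataset.matrix(ROLE_STUDY)
    rows = []
    removed = []
    for m in study.columns:
        x = study[m].dropna().to_numpy()
        b = blanks[m].dropna().to_numpy()
        method = "exact" if (min(len(x), len(b)) < 8 and len(np.unique(np.concatenate([x, b]))) == len(x) + len(b)) else "asymptotic"
        p = float(stats.mannwhitneyu(x, b, alternative="two-sided", method=method).pvalue)
        ratio = float(np.median(x) / np.median(b))
        drop = (p > alpha) or (ratio < 1.0)
        rows.append((m, "blank", "wilcoxon_p", p, drop))
        rows.append((m, "blank", "median_ratio", ratio, drop))
        if drop:
            removed.append(m)
    table = pd.DataFrame(
        rows, columns=["metabolite", "filter", "statistic", "value", "removed"]
    )
    retained = [m for m in study.columns if m not in set(removed)]
    return FilterReport("blank", table, removed, retained)


def apply_filters(
    dataset: TimeCourseDataset, reports: Sequence[FilterReport]
) -> TimeCourseDataset:
    """Drop every metabolite removed by any of the given filter reports."""
    removed = set()
    for r in reports:
        removed |= set(r.removed)
    return dataset.restrict([m for m in dataset.metabolites if m not in removed])


def impute_missing(
    matrix: pd.DataFrame, method: str = "iterative", seed: int = 0
) -> pd.DataFrame:
    """Fill missing entries by iterative chained regression (MICE-style).

    Observed entries are returned unchanged; the result is deterministic for
    a given seed. A fully missing column is an error. ``method="median"``
    provides a cheap fallback.
    """
    if matrix.isna().sum().sum() == 0:
        return matrix.copy()
    fully_missing = matrix.columns[matrix.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"metabolite fully missing, cannot impute: {fully_missing[0]!r}")
    frac = matrix.isna().mean(axis=0)
    if (frac >= 0.5).any():
        bad = frac.index[frac >= 0.5][0]
        raise ValueError(f"metabolite {bad!r} has >= 50% missing values")
    if method == "median":
        return matrix.fillna(matrix.median(axis=0))
    if method != "iterative":
        raise ValueError(f"unknown imputation method: {method!r}")
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    imputer = IterativeImputer(
        random_state=seed,
        max_iter=10,
        n_nearest_features=min(20, matrix.shape[1] - 1) or None,
        sample_posterior=False,
        keep_empty_features=False,
    )
    filled = imputer.fit_transform(matrix.to_numpy())
    out = pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)
    # guarantee observed entries untouched regardless of backend behavior
    out = out.where(matrix.isna(), matrix)
    return out


def log10_autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """log10-transform then standardize each column to mean 0, SD 1 (ddof=1).

    Non-positive values are an error (with location); constant columns are
    excluded with a warning rather than producing divisions by zero.
    """
    arr = matrix.to_numpy(dtype=float)
    bad = np.argwhere(~(arr > 0) | ~np.isfinite(arr))
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"non-positive or missing value at sample {matrix.index[r]!r}, "
            f"metabolite {matrix.columns[c]!r}"
        )
    logged = np.log10(arr)
    sd = logged.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        names = list(matrix.columns[constant])
        warnings.warn(f"excluding constant columns from autoscaling: {names}")
    keep = ~constant
    scaled = (logged[:, keep] - logged[:, keep].mean(axis=0)) / sd[keep]
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns[keep])


def timecourse_zscores(dataset: TimeCourseDataset, log10: bool = True) -> pd.DataFrame:
    """Metabolite x timepoint z-scored mean trajectories.

    For each metabolite the across-subject mean at each timepoint is
    computed, then that vector is z-scored (mean 0, SD 1 across timepoints,
    ddof=1) — the representation fuzzy temporal clustering operates on.
    Metabolites with a constant mean profile are excluded with a warning.
    """
    _, tps, cube = dataset.study_array()
    if log10:
        if np.nanmin(cube) <= 0:
            raise ValueError("log10 requires strictly positive intensities")
        cube = np.log10(cube)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        prof = np.nanmean(cube, axis=0)  # timepoint x metabolite
    sd = prof.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        names = [m for m, c in zip(dataset.metabolites, constant) if c]
        warnings.warn(f"excluding constant-profile metabolites: {names}")
    keep = ~constant
    z = (prof[:, keep] - prof[:, keep].mean(axis=0)) / sd[keep]
    mets = [m for m, k in zip(dataset.metabolites, keep) if k]
    return pd.DataFrame(
        z.T, index=pd.Index(mets, name="metabolite"), columns=[f"{t:g}" for t in tps]
    )
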