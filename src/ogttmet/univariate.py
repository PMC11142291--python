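"""Two-step univariate selection for oGTT metabolite responses.

Step 1 screens metabolites for an overall time effect during the glucose
challenge with a linear mixed model (subject random intercept, 5-level time
factor), Benjamini-Hochberg corrected across metabolites. Step 2 fits, for
metabolites passing the screen, a linear model of the windowed AUC on snack
group adjusted for the fasting (time 0) value, and reports the group
p-value together with Hedge's g on the AUCs, group means +/- SD and the
percent difference.

For balanced complete trajectories the mixed-model likelihood-ratio test has
a closed form: with SS_time the between-timepoint and SS_resid the
subject-by-time interaction sum of squares,

    LRT = n_subjects * (T - 1) * ln(1 + SS_time / SS_resid),  df = T - 1.

This is the exact ML likelihood ratio for the balanced random-intercept
model (the subject variance component cancels) and is verified against
statsmodels MixedLM in the test suite. Unbalanced data falls back to a
numerical MixedLM fit; non-convergence falls back to the repeated-measures
ANOVA F test, recorded per metabolite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .auc import AUCFeatureTable
from .data import GROUPS, TimeCourseDataset


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hedges_g(x, y) -> float:
    """Bias-corrected standardized mean difference mean(x)-mean(y).

    g = (mean(x) - mean(y)) / s_pooled * J with pooled sample SD and the
    small-sample correction J = 1 - 3 / (4(n_x + n_y) - 9).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs n >= 2")
    s2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if s2 <= 0:
        raise ValueError("zero pooled SD: effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (nx + ny) - 9.0)
    return float((x.mean() - y.mean()) / np.sqrt(s2) * j)


def _balanced_time_lrt(cube_met: np.ndarray) -> tuple[float, float]:
    """Closed-form mixed-model LRT of the time factor on one metabolite.

    ``cube_met`` is a complete subject x timepoint matrix. Returns
    (statistic, p) with the statistic ~ chi2(T-1) under no time effect.
    """
    n, T = cube_met.shape
    grand = cube_met.mean()
    col_means = cube_met.mean(axis=0)
    row_means = cube_met.mean(axis=1)
    ss_time = n * np.sum((col_means - grand) ** 2)
    resid = cube_met - row_means[:, None] - col_means[None, :] + grand
    ss_resid = np.sum(resid**2)
    if ss_resid <= 0:
        return np.inf, 0.0
    lrt = n * (T - 1) * np.log1p(ss_time / ss_resid)
    return float(lrt), float(stats.chi2.sf(lrt, T - 1))


def _balanced_time_f(cube_met: np.ndarray) -> tuple[float, float]:
    """Repeated-measures ANOVA F test of the time factor (balanced data)."""
    n, T = cube_met.shape
    grand = cube_met.mean()
    col_means = cube_met.mean(axis=0)
    row_means = cube_met.mean(axis=1)
    ss_time = n * np.sum((col_means - grand) ** 2)
    resid = cube_met - row_means[:, None] - col_means[None, :] + grand
    ss_resid = np.sum(resid**2)
    df1, df2 = T - 1, (n - 1) * (T - 1)
    f = (ss_time / df1) / (ss_resid / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def _mixedlm_time_lrt(values: np.ndarray, subject: np.ndarray, time: np.ndarray):
    """Numerical ML mixed-model LRT for unbalanced trajectories."""
    import statsmodels.api as sm

    df = pd.DataFrame({"y": values, "subject": subject, "time": time.astype(str)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM.from_formula("y ~ C(time)", groups="subject", data=df).fit(
            reml=False
        )
        null = sm.MixedLM.from_formula("y ~ 1", groups="subject", data=df).fit(
            reml=False
        )
    if not (full.converged and null.converged):
        raise RuntimeError("MixedLM did not converge")
    lrt = 2.0 * (full.llf - null.llf)
    dfree = df["time"].nunique() - 1
    return float(lrt), float(stats.chi2.sf(max(lrt, 0.0), dfree))


def time_effect_screen(
    dataset: TimeCourseDataset,
    log10: bool = True,
    fdr_level: float = 0.05,
    statistic: str = "lrt",
) -> pd.DataFrame:
    """Per-metabolite overall time-effect test with BH-FDR selection.

    Returns a DataFrame indexed by metabolite with columns ``pvalue``,
    ``fdr_p``, ``selected`` and ``method``. ``statistic`` is ``"lrt"``
    (mixed-model likelihood ratio, default) or ``"f"`` (repeated-measures
    ANOVA F).
    """
    subjects, tps, cube = dataset.study_array()
    if len(subjects) < 2:
        raise ValueError("time-effect screen needs >= 2 subjects")
    if log10:
        if np.nanmin(cube) <= 0:
            raise ValueError("log10 requires strictly positive intensities")
        cube = np.log10(cube)
    rows = []
    for j, m in enumerate(dataset.metabolites):
        mat = cube[:, :, j]
        complete = ~np.isnan(mat).any(axis=1)
        method = statistic
        if complete.all():
            stat_fn = _balanced_time_lrt if statistic == "lrt" else _balanced_time_f
            _, p = stat_fn(mat)
        else:
            obs = ~np.isnan(mat)
            subj_idx, t_idx = np.where(obs)
            try:
                _, p = _mixedlm_time_lrt(
                    mat[obs],
                    np.asarray(subjects)[subj_idx],
                    tps[t_idx],
                )
                method = "mixedlm_lrt"
            except Exception:
                _, p = _balanced_time_f(mat[complete])
                method = "rm_anova_fallback"
        rows.append((m, p, method))
    out = pd.DataFrame(rows, columns=["metabolite", "pvalue", "method"]).set_index(
        "metabolite"
    )
    out["fdr_p"] = bh_adjust(out["pvalue"].to_numpy())
    out["selected"] = out["fdr_p"] < fdr_level
    return out[["pvalue", "fdr_p", "selected", "method"]]


def group_effect_auc(
    auc_features: AUCFeatureTable,
    window: str,
    metabolites=None,
    baseline_adjust: bool = True,
    groups: tuple[str, str] = GROUPS,
) -> pd.DataFrame:
    """Snack-group contrast on windowed AUCs, adjusted for the fasting value.

    Fits ``auc ~ group + time0`` per metabolite (OLS; time0 dropped when
    ``baseline_adjust=False``) and reports the group-coefficient p-value,
    Hedge's g of group 1 vs group 2 AUCs, group means +/- SD, and the percent
    difference (mean_1 - mean_2) / mean_2 * 100.
    """
    g1, g2 = groups
    sub = auc_features.table[auc_features.table["window"] == window]
    if sub.empty:
        raise ValueError(f"window {window!r} not present in the AUC table")
    if metabolites is not None:
        sub = sub[sub["metabolite"].isin(set(metabolites))]
    rows = []
    for m, grp in sub.groupby("metabolite", sort=True):
        x1 = grp.loc[grp["group"] == g1, "auc"].to_numpy()
        x2 = grp.loc[grp["group"] == g2, "auc"].to_numpy()
        if len(x1) < 3 or len(x2) < 3:
            raise ValueError(f"fewer than 3 subjects per group for {m!r}")
        ind = (grp["group"] == g1).to_numpy(dtype=float)
        y = grp["auc"].to_numpy()
        cols = [np.ones_like(y), ind]
        if baseline_adjust:
            cols.append(grp["time0"].to_numpy())
        X = np.column_stack(cols)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(y) - X.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t = beta[1] / np.sqrt(cov[1, 1])
        p = 2.0 * stats.t.sf(abs(t), dof)
        g = hedges_g(x1, x2)
        m1, m2 = x1.mean(), x2.mean()
        rows.append(
            {
                "metabolite": m,
                "window": window,
                "pvalue": float(p),
                "g": g,
                "direction": "higher" if g > 0 else ("lower" if g < 0 else "equal"),
                f"mean_{g1}": m1,
                f"sd_{g1}": x1.std(ddof=1),
                f"mean_{g2}": m2,
                f"sd_{g2}": x2.std(ddof=1),
                "pct_difference": (m1 - m2) / m2 * 100.0 if m2 != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("metabolite")


def group_effects_all_windows(
    auc_features: AUCFeatureTable,
    metabolites=None,
    baseline_adjust: bool = True,
) -> pd.DataFrame:
    """group_effect_auc over every window present, concatenated long-form."""
    frames = [
        group_effect_auc(auc_features, w, metabolites, baseline_adjust).reset_index()
        for w in auc_features.table["window"].unique()
    ]
    return pd.concat(frames, ignore_index=True)
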