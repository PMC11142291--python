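"""Group-wise correlations of metabolite AUCs with insulin sensitivity.

For variables selected by the group-discriminant PLS-DA loading rule,
Pearson correlations with the Matsuda Index are computed separately in each
snack arm (with Shapiro-Wilk normality flags), and the almond-vs-cracker
difference in correlation is tested with Fisher's r-to-z transformation:

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import GROUPS


def pearson_with_normality(x, y, alpha_sw: float = 0.05) -> dict:
    """Pearson r with two-sided p plus Shapiro-Wilk normality flags.

    Non-normal variables are flagged, not dropped — the correlation is
    still computed and the flag surfaced for the analyst.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired input with n >= 3 required")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    sw_x = float(stats.shapiro(x).pvalue)
    sw_y = float(stats.shapiro(y).pvalue)
    return {
        "r": float(r),
        "p": float(p),
        "n": len(x),
        "shapiro_p_x": sw_x,
        "shapiro_p_y": sw_y,
        "normal_x": sw_x >= alpha_sw,
        "normal_y": sw_y >= alpha_sw,
    }


def fisher_r_to_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample comparison of correlation coefficients via Fisher's z.

    Returns (z, two-sided p). Requires |r| < 1 and n >= 4 per group.
    """
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_group_correlations(
    features: pd.DataFrame,
    clinical: pd.Series,
    group: pd.Series,
    variables=None,
    groups: tuple[str, str] = GROUPS,
    alpha_sw: float = 0.05,
) -> pd.DataFrame:
    """Per-variable group-wise Pearson r vs the clinical index + Fisher z.

    ``features`` is subject x variable; ``clinical`` and ``group`` are
    subject-indexed. Subjects with a missing clinical value are dropped.
    """
    variables = list(variables) if variables is not None else list(features.columns)
    g1, g2 = groups
    rows = []
    for v in variables:
        row: dict = {"variable": v}
        stats_per_group = {}
        ok = True
        for g in (g1, g2):
            idx = features.index[(group.loc[features.index] == g)]
            sub = pd.concat([features.loc[idx, v], clinical.loc[idx]], axis=1).dropna()
            if len(sub) < 4:
                ok = False
                break
            res = pearson_with_normality(sub.iloc[:, 0], sub.iloc[:, 1], alpha_sw)
            stats_per_group[g] = res
            row[f"r_{g}"] = res["r"]
            row[f"p_{g}"] = res["p"]
            row[f"n_{g}"] = res["n"]
            row[f"normal_{g}"] = res["normal_x"] and res["normal_y"]
        if not ok:
            continue
        z, p = fisher_r_to_z_compare(
            stats_per_group[g1]["r"], stats_per_group[g1]["n"],
            stats_per_group[g2]["r"], stats_per_group[g2]["n"],
        )
        row["z_diff"] = z
        row["p_diff"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable") if rows else pd.DataFrame()
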