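"""Chemical-class enrichment from per-metabolite p-values.

A chemical class is enriched when the p-values of its members deviate from
the Uniform(0,1) distribution expected under no effect, assessed by a
one-sample Kolmogorov-Smirnov test per class with Benjamini-Hochberg FDR
control across classes. Altered members (raw p below alpha) and the
majority direction of their effect sizes summarize what drives each hit —
the set-level analogue of asking which lipid or amino-acid families shift
between snack groups in a given oGTT window.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import bh_adjust


def ks_uniform_test(pvalues) -> tuple[float, float]:
    """One-sample KS test of member p-values against Uniform(0, 1).

    Returns (D, p) with D = sup |F_n(x) - x|. Exact small-sample distribution
    for n < 10, asymptotic Kolmogorov distribution otherwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    method = "exact" if p.size < 10 else "asymp"
    res = stats.ks_1samp(p, stats.uniform.cdf, method=method)
    return float(res.statistic), float(res.pvalue)


def chemical_enrichment(
    results: pd.DataFrame,
    class_map: dict[str, str],
    min_size: int = 3,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class KS enrichment over a metabolite result table.

    ``results`` needs columns ``metabolite``, ``pvalue`` and ``g`` (signed
    effect size). Classes with at least ``min_size`` mapped members are
    tested; class direction is the majority sign of the altered members'
    effect sizes ("higher" / "lower" in the first group, "mixed" on ties,
    "none" when nothing is altered).

    Returns (class table, altered-member table).
    """
    df = results.copy()
    if "metabolite" not in df.columns:
        df = df.reset_index()
    df = df[df["metabolite"].isin(class_map)]
    df["chem_class"] = df["metabolite"].map(class_map)

    rows, member_rows = [], []
    for cls, grp in df.groupby("chem_class", sort=True):
        if len(grp) < min_size:
            continue
        d, p_ks = ks_uniform_test(grp["pvalue"].to_numpy())
        altered = grp[grp["pvalue"] < alpha]
        pos = int((altered["g"] > 0).sum())
        neg = int((altered["g"] < 0).sum())
        if pos + neg == 0:
            direction = "none"
        elif pos == neg:
            direction = "mixed"
        else:
            direction = "higher" if pos > neg else "lower"
        rows.append(
            {
                "chem_class": cls,
                "size": len(grp),
                "ks_D": d,
                "pvalue": p_ks,
                "n_altered": len(altered),
                "direction": direction,
            }
        )
        for _, r in altered.iterrows():
            member_rows.append(
                {
                    "chem_class": cls,
                    "metabolite": r["metabolite"],
                    "pvalue": r["pvalue"],
                    "g": r["g"],
                    "direction": "higher" if r["g"] > 0 else "lower",
                }
            )
    if not rows:
        warnings.warn("no chemical class reaches min_size; empty enrichment result")
        empty = pd.DataFrame(
            columns=["chem_class", "size", "ks_D", "pvalue", "fdr_p", "n_altered", "direction"]
        )
        return empty, pd.DataFrame(columns=["chem_class", "metabolite", "pvalue", "g", "direction"])
    table = pd.DataFrame(rows)
    table["fdr_p"] = bh_adjust(table["pvalue"].to_numpy())
    table = table[
        ["chem_class", "size", "ks_D", "pvalue", "fdr_p", "n_altered", "direction"]
    ].sort_values("fdr_p", kind="stable").reset_index(drop=True)
    members = pd.DataFrame(member_rows)
    return table, members


def enrichment_by_window(
    window_results: pd.DataFrame,
    class_map: dict[str, str],
    min_size: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run class enrichment separately for each AUC window.

    ``window_results`` is a long table with columns metabolite, window,
    pvalue, g (as produced by the univariate module across windows).
    """
    frames = []
    for w, grp in window_results.groupby("window", sort=False):
        table, _ = chemical_enrichment(grp, class_map, min_size, alpha)
        table.insert(0, "window", w)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)
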