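"""dCT / ddCT relative quantification and group comparison for RT-qPCR.

Expression is normalized to a reference gene (dCT = CT_target -
CT_reference), then to a control group (ddCT = dCT_sample -
mean dCT of the control group); relative expression is 2^-ddCT.
Group comparisons use one-way ANOVA followed by Tukey's HSD post hoc
test, with the usual star annotations (* <= 0.05, ** <= 0.01,
*** <= 0.001).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["delta_ct", "ddct_fold_change", "anova_tukey", "p_to_stars"]

REQUIRED_COLUMNS = ("sample", "group", "ct_target", "ct_reference")


def delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Attach ``dct = ct_target - ct_reference`` per sample.

    Rows with a missing reference CT are dropped with a warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table lacks column(s): {missing}")
    out = table.copy()
    bad = out["ct_reference"].isna() | out["ct_target"].isna()
    if bad.any():
        warnings.warn(
            f"skipping {int(bad.sum())} record(s) with missing CT values",
            stacklevel=2,
        )
        out = out[~bad]
    out = out.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    return out


def ddct_fold_change(table: pd.DataFrame, control_group: str):
    """Fold changes 2^-ddCT relative to a control group.

    The control aggregate is the arithmetic mean of the control group's
    dCT values (the geometric mean on the linear scale), so the fold of
    the control aggregate is exactly 1.  Returns ``(per_sample,
    group_summary)``; the summary reports mean +/- SD of the per-sample
    folds per group.
    """
    if "dct" not in table.columns:
        table = delta_ct(table)
    groups = set(table["group"])
    if control_group not in groups:
        raise ValueError(
            f"control group {control_group!r} not found (have {sorted(groups)})"
        )
    control_dct = float(table.loc[table["group"] == control_group, "dct"].mean())
    out = table.copy()
    out["ddct"] = out["dct"] - control_dct
    out["fold"] = np.exp2(-out["ddct"])
    summary = (
        out.groupby("group", sort=False)["fold"]
        .agg(mean_fold="mean", sd_fold="std", n="size")
        .reset_index()
    )
    summary.attrs["control_group"] = control_group
    return out, summary


def p_to_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def anova_tukey(values, groups, pairwise: bool = True):
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    Returns ``(f_stat, p_omnibus, pairwise)`` where pairwise is a frame
    with one row per group pair: mean difference, Tukey-adjusted p from
    the studentized range distribution, and a star annotation.  All
    groups constant with equal means yields F = 0, p = 1.  With
    ``pairwise=False`` only the omnibus test is computed (pairwise is
    ``None``).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == lev] for lev in levels]
    for lev, s in zip(levels, samples):
        if len(s) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 values")
    within_var = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    means = [s.mean() for s in samples]
    if within_var == 0:
        if np.ptp(means) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat, p = sps.f_oneway(*samples)
        f_stat, p = float(f_stat), float(p)
    if not pairwise:
        return f_stat, p, None
    if within_var == 0:
        # degenerate: Tukey p mirrors the omnibus outcome per pair
        rows = [
            {
                "group1": levels[i],
                "group2": levels[j],
                "mean_diff": means[i] - means[j],
                "p_tukey": 1.0 if means[i] == means[j] else 0.0,
            }
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
    else:
        res = sps.tukey_hsd(*samples)
        rows = [
            {
                "group1": levels[i],
                "group2": levels[j],
                "mean_diff": means[i] - means[j],
                "p_tukey": float(res.pvalue[i, j]),
            }
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
    table = pd.DataFrame(rows)
    table["stars"] = table["p_tukey"].map(p_to_stars)
    return f_stat, p, table
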