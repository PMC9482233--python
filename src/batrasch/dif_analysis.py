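"""Differential item functioning via two-way ANOVA of standardized residuals.

For each item, residuals z_ni are modelled by a fixed-effects two-way
ANOVA on person group (e.g. the younger/older median-age split) and class
interval along the latent trait. A significant group main effect indicates
uniform DIF (a constant shift at every trait level); a significant
group x interval interaction indicates non-uniform DIF (the shift varies
with the trait). Type II sums of squares; Bonferroni across items at base
alpha 0.01.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .fit_diagnostics import ResidualMatrix

__all__ = ["DIFReport", "dif_anova"]


@dataclasses.dataclass
class DIFReport:
    table: pd.DataFrame          # per item: F/p for uniform and non-uniform DIF, flags
    group_variable: str
    alpha: float
    bonferroni_alpha: float
    merged_intervals: bool       # intervals were merged to fill empty cells


def _fill_cells(groups: np.ndarray, intervals: np.ndarray) -> tuple[np.ndarray, bool]:
    """Merge class intervals downward until every group x interval cell is filled."""
    intervals = intervals.copy()
    merged = False
    while intervals.max() > 0:
        tab = pd.crosstab(groups, intervals)
        if (tab.to_numpy() > 0).all() and tab.shape[1] == intervals.max() + 1:
            break
        # merge the highest sparse interval into its lower neighbour
        sparse = intervals.max()
        for c in range(intervals.max() + 1):
            col = (intervals == c)
            if not all((col & (groups == g)).any() for g in np.unique(groups)):
                sparse = c
                break
        target = sparse - 1 if sparse > 0 else sparse + 1
        intervals[intervals == sparse] = target
        _, intervals = np.unique(intervals, return_inverse=True)
        merged = True
        warnings.warn("merged class intervals to fill empty DIF cells")
    return intervals, merged


def dif_anova(
    res: ResidualMatrix,
    groups: np.ndarray,
    intervals: np.ndarray,
    group_variable: str = "group",
    alpha: float = 0.01,
) -> DIFReport:
    """Per-item two-way ANOVA of residuals on group and class interval.

    ``groups`` and ``intervals`` are aligned with the residual rows
    (non-extreme persons).
    """
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    intervals, merged = _fill_cells(groups, np.asarray(intervals))
    if intervals.max() + 1 < 2:
        raise ValueError("need at least two class intervals after merging")
    rows = []
    for j, item in enumerate(res.items):
        df = pd.DataFrame({
            "z": res.z[:, j],
            "grp": pd.Categorical(groups),
            "ci": pd.Categorical(intervals),
        })
        fit = smf.ols("z ~ C(grp) * C(ci)", data=df).fit()
        an = sm.stats.anova_lm(fit, typ=2)
        rows.append((
            item,
            float(an.loc["C(grp)", "F"]), float(an.loc["C(grp)", "PR(>F)"]),
            float(an.loc["C(grp):C(ci)", "F"]), float(an.loc["C(grp):C(ci)", "PR(>F)"]),
        ))
    table = pd.DataFrame(
        rows, columns=["item", "uniform_F", "uniform_p", "nonuniform_F", "nonuniform_p"]
    ).set_index("item")
    bonf = alpha / len(res.items)
    table["uniform_flag"] = table["uniform_p"] < bonf
    table["nonuniform_flag"] = table["nonuniform_p"] < bonf
    return DIFReport(table, group_variable, alpha, bonf, merged)
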