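"""Scalar group-level analyses: per-participant means, ANOVAs, post hocs."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .preprocess import CleanTimecourse

__all__ = [
    "AnovaResult",
    "summarize",
    "oneway_anova",
    "twoway_anova",
    "posthoc_pairwise",
]

log = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float


def summarize(clean: Sequence[CleanTimecourse]) -> pd.DataFrame:
    """Mean pupil change per participant x block over the observed span."""
    rows = []
    for c in clean:
        vals = c.dpd_mm[~np.isnan(c.dpd_mm)]
        if len(vals) == 0:
            log.warning("empty series for %s block %s; row omitted",
                        c.participant_id, c.block_id)
            continue
        rows.append({
            "participant_id": c.participant_id,
            "group": c.group_label,
            "block_id": c.block_id,
            "mean_dpd_mm": float(np.mean(vals)),
        })
    return pd.DataFrame(rows, columns=["participant_id", "group", "block_id",
                                       "mean_dpd_mm"])


def oneway_anova(values: np.ndarray, factor: np.ndarray) -> AnovaResult:
    """Classical fixed-effects between-groups one-way ANOVA."""
    values = np.asarray(values, dtype=float)
    factor = np.asarray(factor)
    levels = pd.unique(factor)
    if len(levels) < 2:
        raise ValueError("factor needs >= 2 levels")
    groups = [values[factor == lv] for lv in levels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each level needs >= 2 observations")
    F, p = sps.f_oneway(*groups)
    df_num = len(levels) - 1
    df_den = len(values) - len(levels)
    return AnovaResult("factor", float(F), float(df_num), float(df_den), float(p))


def twoway_anova(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    names: tuple[str, str] = ("A", "B"),
) -> list[AnovaResult]:
    """Two-way fixed-effects ANOVA with interaction, Type II sums of squares.

    Type II handles the study's unbalanced cells; in a balanced design it
    reduces to the classical decomposition.  Cells with no observations, or
    a design with one observation per cell (interaction untestable), raise.
    """
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "fa": pd.Categorical(factor_a),
        "fb": pd.Categorical(factor_b),
    })
    counts = df.groupby(["fa", "fb"], observed=False).size()
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"empty design cells: {list(empty.index)}")
    if (counts == 1).all():
        raise ValueError("one observation per cell; interaction untestable")
    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = float(table.loc["Residual", "df"])
    out = []
    for row_name, effect in (("C(fa)", names[0]), ("C(fb)", names[1]),
                             ("C(fa):C(fb)", f"{names[0]}x{names[1]}")):
        out.append(AnovaResult(
            effect=effect,
            F=float(table.loc[row_name, "F"]),
            df_num=float(table.loc[row_name, "df"]),
            df_den=df_den,
            p=float(table.loc[row_name, "PR(>F)"]),
        ))
    return out


def posthoc_pairwise(
    values: np.ndarray,
    factor: np.ndarray,
    method: str = "holm",
) -> pd.DataFrame:
    """All pairwise Welch t-tests between factor levels with p adjustment."""
    values = np.asarray(values, dtype=float)
    factor = np.asarray(factor)
    levels = list(pd.unique(factor))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups for pairwise comparisons")
    rows = []
    for a, b in itertools.combinations(levels, 2):
        va, vb = values[factor == a], values[factor == b]
        t, p = sps.ttest_ind(va, vb, equal_var=False)
        rows.append({"group_a": a, "group_b": b,
                     "t": float(t), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"], method=method)[1]
    return table
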