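"""Factorial cohort statistics: per-timepoint two-way ANOVA and post-hoc tests.

Each measure is analysed independently at each timepoint with a two-factor
(surgery x diet) ANOVA including the interaction.  For unbalanced cells Type
II sums of squares are used (these reduce to the classical decomposition when
the design is balanced).  When the interaction is significant at alpha, the
four within-level comparisons (sham vs. AAB within each diet, chow vs. WD
within each surgery) are evaluated with pooled-variance two-sample t-tests and
Bonferroni correction (m = 4, adjusted p = min(1, 4p)).  Summaries are sample
mean and SD (n-1 denominator) per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "two_way_anova",
    "bonferroni_posthoc",
    "summarize",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
SURGERY_LEVELS = ("sham", "aab")
DIET_LEVELS = ("chow", "wd")


@dataclass(frozen=True)
class EffectStats:
    ss: float
    df: int
    f: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA decomposition for one (week, measure) selection."""

    week: int
    measure: str
    effects: dict[str, EffectStats]       # keys: surgery, diet, interaction
    residual_ss: float
    residual_df: int
    cell_ns: dict[tuple[str, str], int]
    ss_type: int = 2

    def p_of(self, effect: str) -> float:
        return self.effects[effect].p


@dataclass(frozen=True)
class PosthocResult:
    comparison: str
    t: float
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    significant: bool


def _select(table: pd.DataFrame, week: int, measure: str) -> pd.DataFrame:
    required = {"surgery", "diet", "week", "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"cohort table lacks columns: {sorted(missing)}")
    sel = table[(table["week"] == week) & (table["measure"] == measure)]
    if sel.empty:
        raise ValidationError(f"no rows for week={week}, measure={measure!r}")
    return sel


def _cell_ns(sel: pd.DataFrame) -> dict[tuple[str, str], int]:
    ns = {}
    for s in SURGERY_LEVELS:
        for d in DIET_LEVELS:
            ns[(s, d)] = int(((sel["surgery"] == s) & (sel["diet"] == d)).sum())
    return ns


def two_way_anova(table: pd.DataFrame, week: int, measure: str) -> AnovaResult:
    """Fit value ~ surgery * diet on one (week, measure) selection and return
    Type II F tests for both main effects and the interaction."""
    sel = _select(table, week, measure)
    ns = _cell_ns(sel)
    empty = [cell for cell, n in ns.items() if n < 2]
    if empty:
        raise ValidationError(f"cells with fewer than 2 animals: {empty}")

    model = smf.ols("value ~ C(surgery) * C(diet)", data=sel).fit()
    tab = sm.stats.anova_lm(model, typ=2)

    def row(name: str) -> EffectStats:
        r = tab.loc[name]
        return EffectStats(
            ss=float(r["sum_sq"]), df=int(r["df"]), f=float(r["F"]), p=float(r["PR(>F)"])
        )

    effects = {
        "surgery": row("C(surgery)"),
        "diet": row("C(diet)"),
        "interaction": row("C(surgery):C(diet)"),
    }
    resid = tab.loc["Residual"]
    return AnovaResult(
        week=week,
        measure=measure,
        effects=effects,
        residual_ss=float(resid["sum_sq"]),
        residual_df=int(resid["df"]),
        cell_ns=ns,
    )


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni_posthoc(
    table: pd.DataFrame,
    week: int,
    measure: str,
    anova: AnovaResult,
    alpha: float = ALPHA,
) -> list[PosthocResult]:
    """Conditional post-hoc family: run only when the ANOVA interaction is
    significant; otherwise return an empty list (with a log note)."""
    if (anova.week, anova.measure) != (week, measure):
        raise ValidationError("ANOVA result does not match the requested selection")
    if anova.p_of("interaction") > alpha:
        logger.info(
            "interaction p=%.3f > %.2f for %s @ week %d: post-hoc not run",
            anova.p_of("interaction"), alpha, measure, week,
        )
        return []
    sel = _select(table, week, measure)

    def cell(s: str, d: str) -> np.ndarray:
        return sel[(sel["surgery"] == s) & (sel["diet"] == d)]["value"].to_numpy()

    comparisons = [
        ("sham_vs_aab_within_chow", cell("sham", "chow"), cell("aab", "chow")),
        ("sham_vs_aab_within_wd", cell("sham", "wd"), cell("aab", "wd")),
        ("chow_vs_wd_within_sham", cell("sham", "chow"), cell("sham", "wd")),
        ("chow_vs_wd_within_aab", cell("aab", "chow"), cell("aab", "wd")),
    ]
    m = len(comparisons)
    out = []
    for label, a, b in comparisons:
        t, p = _pooled_t(a, b)
        p_adj = min(1.0, m * p)
        out.append(
            PosthocResult(
                comparison=label, t=t, p_raw=p, p_adjusted=p_adj,
                m_comparisons=m, significant=p_adj <= alpha,
            )
        )
    return out


def summarize(table: pd.DataFrame, week: int, measure: str) -> pd.DataFrame:
    """Per-cell mean, sample SD and n; SD is missing (NaN) for n = 1 cells."""
    sel = _select(table, week, measure)
    rows = []
    for s in SURGERY_LEVELS:
        for d in DIET_LEVELS:
            v = sel[(sel["surgery"] == s) & (sel["diet"] == d)]["value"].to_numpy()
            if v.size == 0:
                continue
            rows.append(
                {
                    "surgery": s,
                    "diet": d,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
                    "n": int(v.size),
                }
            )
    return pd.DataFrame(rows)
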