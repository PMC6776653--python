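"""ROI-level group statistics.

Independent two-sample t-tests (pooled variance by default, matching a
37-degree-of-freedom comparison of 19 vs 20 subjects) with Cohen's d, a
two-way ANOVA (group x ROI) over the hedonic network, Pearson correlations
between PET and clinical measures, and Shapiro-Wilk normality checks.
Standard fits are delegated to scipy/statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .atlas import RegionAtlas
from .cohort import SubjectRecord

__all__ = [
    "GroupComparison",
    "AnovaTable",
    "ttest_two_sample",
    "cohen_d_from_summary",
    "cohen_d_from_raw",
    "anova_two_way",
    "pearson_correlation",
    "shapiro_wilk_check",
    "striatal_comparison",
    "region_set_comparisons",
    "hedonic_long_table",
]

log = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p_value: float
    cohen_d: float
    variant: str = "pooled"


@dataclass
class AnovaTable:
    """Two-way ANOVA results: F, numerator/denominator df and p per factor."""

    factors: list[str]
    f_values: dict[str, float]
    df_num: dict[str, int]
    df_den: int
    p_values: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "F": self.f_values,
            "df_num": self.df_num,
            "df_den": {f: self.df_den for f in self.factors},
            "p": self.p_values,
        }).loc[self.factors]


def ttest_two_sample(values_a, values_b, variant: str = "pooled") -> GroupComparison:
    """Independent two-sample t-test (two-sided).

    ``variant`` is "pooled" (equal-variance; df = n_a + n_b - 2) or "welch".
    The sign of t follows the sign of mean_a - mean_b.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            raise ValueError("t undefined: zero variance in both groups with equal means")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = a.size + b.size - 2 if variant == "pooled" else float(res.df)
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        n_a=int(a.size), n_b=int(b.size),
        t_statistic=float(res.statistic), df=float(df), p_value=float(res.pvalue),
        cohen_d=cohen_d_from_raw(a, b), variant=variant,
    )


def cohen_d_from_raw(values_a, values_b) -> float:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    return cohen_d_from_summary(a.mean(), sd_a / np.sqrt(a.size), a.size,
                                b.mean(), sd_b / np.sqrt(b.size), b.size)


def cohen_d_from_summary(mean_a: float, sem_a: float, n_a: int,
                         mean_b: float, sem_b: float, n_b: int) -> float:
    """|mean difference| / pooled SD, with SD reconstructed as SEM * sqrt(n).

    Pooled SD uses (n - 1) weights, the convention that reproduces published
    effect sizes computed from summary tables.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    sd_a = sem_a * np.sqrt(n_a)
    sd_b = sem_b * np.sqrt(n_b)
    pooled = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD; Cohen's d undefined")
    return float(abs(mean_a - mean_b) / pooled)


def anova_two_way(long_table: pd.DataFrame, dependent: str = "bpnd",
                  factors: tuple[str, str] = ("group", "roi"),
                  ss_type: int = 2) -> AnovaTable:
    """Two-way ANOVA with interaction on a long-format table.

    Type-II sums of squares by default (efficient when the interaction is
    null, robust to mild imbalance).  Each factor must have >= 2 levels.
    """
    fa, fb = factors
    for f in factors:
        if long_table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    model = ols(f"{dependent} ~ C({fa}) * C({fb})", data=long_table).fit()
    table = anova_lm(model, typ=ss_type)
    name_map = {f"C({fa})": fa, f"C({fb})": fb, f"C({fa}):C({fb})": f"{fa}:{fb}"}
    df_den = int(table.loc["Residual", "df"])
    factors_out = [fa, fb, f"{fa}:{fb}"]
    fvals, dfn, pvals = {}, {}, {}
    for raw, nice in name_map.items():
        fvals[nice] = float(table.loc[raw, "F"])
        dfn[nice] = int(table.loc[raw, "df"])
        pvals[nice] = float(table.loc[raw, "PR(>F)"])
    return AnovaTable(factors=factors_out, f_values=fvals, df_num=dfn,
                      df_den=df_den, p_values=pvals)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value."""
    r, p = stats.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(r), float(p)


def shapiro_wilk_check(values, alpha: float = 0.05) -> tuple[float, float]:
    """Shapiro-Wilk W and p; logs a warning when normality is rejected.

    Valid for 3 <= n <= 5000; a constant vector is an error.
    """
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    w, p = stats.shapiro(v)
    if p < alpha:
        log.warning("Shapiro-Wilk rejects normality (W=%.3f, p=%.3g)", w, p)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# cohort-level conveniences


def _group_values(records: list[SubjectRecord], regions: list[str]) -> tuple[np.ndarray, np.ndarray]:
    pat = np.array([r.regional_bpnd.loc[regions].mean() for r in records if r.group == "patient"])
    con = np.array([r.regional_bpnd.loc[regions].mean() for r in records if r.group == "control"])
    return pat, con


def striatal_comparison(records: list[SubjectRecord], atlas: RegionAtlas,
                        variant: str = "pooled") -> GroupComparison:
    """Patient-vs-control comparison of the subject-level striatal mean BP_ND."""
    pat, con = _group_values(records, atlas.subsets["striatum"])
    return ttest_two_sample(pat, con, variant=variant)


def region_set_comparisons(records: list[SubjectRecord], atlas: RegionAtlas,
                           variant: str = "pooled") -> pd.DataFrame:
    """Group comparison per named subset (striatum, dorsal/ventral, hedonic)."""
    rows = {}
    for name, regions in atlas.subsets.items():
        pat, con = _group_values(records, regions)
        c = ttest_two_sample(pat, con, variant=variant)
        rows[name] = {
            "mean_patient": c.mean_a, "sem_patient": c.sem_a, "n_patient": c.n_a,
            "mean_control": c.mean_b, "sem_control": c.sem_b, "n_control": c.n_b,
            "t": c.t_statistic, "df": c.df, "p": c.p_value, "cohen_d": c.cohen_d,
        }
    return pd.DataFrame(rows).T


def hedonic_long_table(records: list[SubjectRecord], atlas: RegionAtlas) -> pd.DataFrame:
    """Long-format subject x ROI x BP_ND table over the hedonic network."""
    rows = []
    for rec in records:
        for roi in atlas.subsets["hedonic_network"]:
            rows.append({"subject_id": rec.subject_id, "group": rec.group,
                         "roi": roi, "bpnd": float(rec.regional_bpnd.loc[roi])})
    return pd.DataFrame(rows)
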