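"""Nonparametric comparison statistics for treatment contrasts.

Per-landscape-pair two-group contrasts use the Mann-Whitney U test with
Benjamini-Hochberg control of the false discovery rate across pairs; a
pooled single-factor contrast uses the Kruskal-Wallis H test; and factorial
questions (e.g. environmental variability crossed with CA rule) use a
two-way aligned-rank-transform (ART) ANOVA, the standard nonparametric
factorial recipe: align the response for each effect by stripping the
estimated other effects, rank the aligned values, and run an ordinary
factorial ANOVA on the ranks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import kruskal, mannwhitneyu
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mannwhitney_bh",
    "kruskal_pooled",
    "art_anova",
    "compare_treatments",
]


def mannwhitney_bh(groups_a: dict, groups_b: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per key, BH-adjusted across keys.

    ``groups_a`` and ``groups_b`` map the same keys (e.g. landscape-pair
    ids) to value lists for the two treatments.
    """
    keys = sorted(groups_a)
    if set(keys) != set(groups_b):
        raise ValueError("the two groups must cover the same keys")
    rows = []
    for key in keys:
        a, b = np.asarray(groups_a[key], float), np.asarray(groups_b[key], float)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty group for key {key!r}")
        res = mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"key": key, "U": float(res.statistic), "p": float(res.pvalue)})
    df = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["p_adj"] = p_adj
    df["significant"] = reject
    return df


def kruskal_pooled(*groups) -> dict:
    """Kruskal-Wallis H across two or more pooled value groups."""
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    stat, p = kruskal(*arrays)
    return {"H": float(stat), "p": float(p)}


def art_anova(data: pd.DataFrame, response: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way aligned-rank-transform ANOVA.

    For each effect (A, B, A:B) the response is aligned by keeping only the
    cell residual plus that effect's cell-mean estimate, the aligned values
    are ranked, and a full factorial OLS ANOVA is run on the ranks; only the
    focal effect's row is reported.
    """
    df = data[[response, factor_a, factor_b]].dropna().copy()
    if df.empty:
        raise ValueError("no data after dropping missing values")
    y = df[response].astype(float)
    grand = y.mean()
    cell = df.groupby([factor_a, factor_b])[response].transform("mean")
    ma = df.groupby(factor_a)[response].transform("mean")
    mb = df.groupby(factor_b)[response].transform("mean")
    resid = y - cell
    aligned = {
        factor_a: resid + (ma - grand),
        factor_b: resid + (mb - grand),
        f"{factor_a}:{factor_b}": resid + (cell - ma - mb + grand),
    }
    focal_row = {
        factor_a: f"C({factor_a})",
        factor_b: f"C({factor_b})",
        f"{factor_a}:{factor_b}": f"C({factor_a}):C({factor_b})",
    }
    rows = []
    for effect, values in aligned.items():
        work = df.assign(_rank=values.rank())
        model = smf.ols(f"_rank ~ C({factor_a}) * C({factor_b})", data=work).fit()
        table = anova_lm(model, typ=2)
        row = table.loc[focal_row[effect]]
        rows.append({"effect": effect, "F": float(row["F"]), "p": float(row["PR(>F)"])})
    return pd.DataFrame(rows)


def compare_treatments(groups_a: dict, groups_b: dict, factorial: pd.DataFrame | None = None,
                       response: str | None = None, factor_a: str | None = None,
                       factor_b: str | None = None) -> dict:
    """Bundle of the comparison battery used for variable-vs-static contrasts.

    Runs the per-key Mann-Whitney + BH table and the pooled Kruskal-Wallis
    test; when a factorial frame is supplied, adds the two-way ART ANOVA.
    """
    report = {
        "mannwhitney": mannwhitney_bh(groups_a, groups_b),
        "kruskal": kruskal_pooled(
            np.concatenate([np.asarray(v, float) for v in groups_a.values()]),
            np.concatenate([np.asarray(v, float) for v in groups_b.values()]),
        ),
    }
    if factorial is not None:
        report["art_anova"] = art_anova(factorial, response, factor_a, factor_b)
    return report
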