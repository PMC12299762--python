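"""Descriptive summaries, treatment change and DC correlation tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SummaryRow:
    """Max / min / mean / sample SD / CV% of one trait under one treatment."""

    max: float
    min: float
    mean: float
    sd: float
    cv: float  # percent; NaN when the mean is zero


def summarize(values) -> SummaryRow:
    """Summary statistics with sample (n−1) SD and CV as percent of mean."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least two finite values to summarize")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return SummaryRow(max=float(x.max()), min=float(x.min()),
                      mean=mean, sd=sd, cv=cv)


def summary_table(values_by_trait: pd.DataFrame) -> pd.DataFrame:
    """One SummaryRow per column, in the table layout of a screen report."""
    rows = {c: vars(summarize(values_by_trait[c])) for c in values_by_trait}
    out = pd.DataFrame(rows).T.loc[:, ["max", "min", "mean", "sd", "cv"]]
    out.index.name = "trait"
    return out


def treatment_change(ck_mean: float, ds_mean: float) -> dict[str, float]:
    """Absolute and percent change of a trait mean from control to stress."""
    if ck_mean == 0:
        raise ValueError("control mean is zero; percent change undefined")
    variation = ds_mean - ck_mean
    return {"variation": variation,
            "percentage_variation": 100.0 * variation / ck_mean}


def dc_correlations(dc: pd.DataFrame, alpha: float = 0.01):
    """Pairwise-complete Pearson correlations among DC columns.

    Returns ``(r, p, flag)`` DataFrames; ``flag`` marks two-tailed
    p < ``alpha``.  Constant columns yield NaN correlations (flagged
    False).  Requires at least three complete rows overall.
    """
    if len(dc.dropna()) < 3:
        raise ValueError("need at least three complete rows for correlations")
    cols = list(dc.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = dc[[cols[i], cols[j]]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) < 3 or x.std() == 0 or y.std() == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = res.statistic, res.pvalue
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    flag = (p_df < alpha) & r_df.notna()
    np.fill_diagonal(flag.values, False)
    return r_df, p_df, flag


def correlations_long(r: pd.DataFrame, p: pd.DataFrame,
                      flag: pd.DataFrame) -> pd.DataFrame:
    """Long-format (trait_a, trait_b, r, p, significant) listing."""
    rows = []
    cols = list(r.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rows.append((a, b, r.loc[a, b], p.loc[a, b], bool(flag.loc[a, b])))
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p", "significant"])


def welch_test(ck_values, ds_values):
    """Plain two-sample Welch t-test between treatments for one trait."""
    res = stats.ttest_ind(np.asarray(ck_values, float),
                          np.asarray(ds_values, float), equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue)}
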