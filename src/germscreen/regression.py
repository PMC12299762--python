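"""Stepwise regression of composite scores on the DC columns.

Classic forward-entry / backward-removal stepwise selection on
partial-F p-values (the SPSS-style procedure, entry p = 0.05, removal
p = 0.10 by default), with a final ordinary-least-squares fit; plus the
per-accession prediction-accuracy summary used to validate the fitted
evaluation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class RegressionModel:
    response: str
    terms: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r: float                        # multiple correlation
    r_squared: float
    entry_p: float
    removal_p: float
    intercept_only: bool = False
    model: object = field(default=None, repr=False, compare=False)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        pred = np.full(len(X), self.coefficients["intercept"], dtype=float)
        for t in self.terms:
            pred += self.coefficients[t] * X[t].to_numpy(dtype=float)
        return pd.Series(pred, index=X.index, name=f"{self.response}_pred")

    def equation(self) -> str:
        parts = [f"{self.coefficients['intercept']:.3f}"]
        parts += [f"{self.coefficients[t]:+.3f}*{t}" for t in self.terms]
        return f"{self.response} = " + " ".join(parts)


def _partial_f_p(y: np.ndarray, X: pd.DataFrame, included: list[str],
                 candidate: str) -> float:
    """Two-sided p of the candidate's partial F when added to the model."""
    cols = included + [candidate]
    fit = sm.OLS(y, sm.add_constant(X[cols])).fit()
    return float(fit.pvalues[candidate])


def stepwise_fit(y, X: pd.DataFrame, entry_p: float = 0.05,
                 removal_p: float = 0.10,
                 response_name: str = "y") -> RegressionModel:
    """Forward-entry / backward-removal stepwise OLS.

    At each step the candidate with the smallest partial-F p-value
    enters if p < ``entry_p`` (ties broken by column order); included
    terms with p > ``removal_p`` are then removed, worst first.  If no
    candidate ever passes entry the result is a flagged intercept-only
    model.
    """
    if entry_p > removal_p:
        raise ValueError("entry_p must not exceed removal_p (cycling risk)")
    data = pd.concat([pd.Series(np.asarray(y, dtype=float),
                                index=X.index, name="__y"), X], axis=1).dropna()
    yv = data["__y"].to_numpy()
    Xv = data[list(X.columns)]
    included: list[str] = []
    while True:
        changed = False
        candidates = [c for c in Xv.columns if c not in included]
        if candidates:
            pvals = [_partial_f_p(yv, Xv, included, c) for c in candidates]
            best = int(np.argmin(pvals))  # argmin keeps first on ties
            if pvals[best] < entry_p:
                included.append(candidates[best])
                changed = True
        if included:
            fit = sm.OLS(yv, sm.add_constant(Xv[included])).fit()
            worst = fit.pvalues[included].astype(float)
            if worst.max() > removal_p:
                included.remove(worst.idxmax())
                changed = True
        if not changed:
            break

    if not included:
        mean = float(yv.mean())
        return RegressionModel(response=response_name, terms=[],
                               coefficients={"intercept": mean}, r=0.0,
                               r_squared=0.0, entry_p=entry_p,
                               removal_p=removal_p, intercept_only=True)
    fit = sm.OLS(yv, sm.add_constant(Xv[included])).fit()
    coefs = {"intercept": float(fit.params["const"])}
    coefs.update({t: float(fit.params[t]) for t in included})
    r2 = float(fit.rsquared)
    return RegressionModel(response=response_name, terms=list(included),
                           coefficients=coefs, r=float(np.sqrt(max(r2, 0.0))),
                           r_squared=r2, entry_p=entry_p,
                           removal_p=removal_p, model=fit)


def prediction_accuracy(observed, predicted) -> pd.DataFrame:
    """Per-case accuracy 100·(1 − |obs − pred|/obs), floored at zero.

    Cases with a non-positive observed value are excluded (listed in
    ``.attrs['excluded']``); summary min and mean are in ``.attrs``.
    """
    obs = pd.Series(observed, dtype=float)
    pred = pd.Series(predicted, dtype=float)
    pred.index = obs.index
    valid = obs > 0
    acc = 100.0 * (1.0 - (obs[valid] - pred[valid]).abs() / obs[valid])
    acc = acc.clip(lower=0.0)
    out = pd.DataFrame({"observed": obs[valid], "predicted": pred[valid],
                        "accuracy_pct": acc})
    out.attrs["excluded"] = list(obs.index[~valid])
    out.attrs["min"] = float(acc.min()) if len(acc) else float("nan")
    out.attrs["mean"] = float(acc.mean()) if len(acc) else float("nan")
    return out


def score_correlations(scores: pd.DataFrame, alpha: float = 0.01):
    """Pearson correlations among the D/WDC/CDC score columns.

    Returns ``(r, p, flag)`` with a unit diagonal and symmetric entries.
    """
    cols = list(scores.columns)
    if len(scores) < 3:
        raise ValueError("need at least three accessions")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(scores[cols[i]], scores[cols[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    flag = (p_df < alpha)
    np.fill_diagonal(flag.values, False)
    return r_df, p_df, flag
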