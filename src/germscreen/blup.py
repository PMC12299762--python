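"""Cross-replicate BLUP of accession D-values.

Model: y_ij = μ + rep_j + g_i + e_ij with replicate fixed and accession
random.  For the balanced two-way design the variance components come
from the ANOVA mean squares (method of moments, identical to REML in
the balanced case):

    σ²_e = MS_residual,   σ²_g = (MS_accession − MS_residual)/r,

and the accession effect is shrunk by the repeatability
h² = σ²_g / (σ²_g + σ²_e/r):  BLUP_i = h²·(ȳ_i· − ȳ··).  Unbalanced
tables fall back to an iterative REML fit (statsmodels MixedLM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BlupResult:
    predictions: pd.DataFrame  # accession, rep-wise D, raw mean, blup_d, flags
    sigma2_g: float            # accession variance component
    sigma2_e: float            # residual variance component
    repeatability: float       # h² = σ²_g/(σ²_g + σ²_e/r)
    grand_mean: float
    method: str                # "anova" (balanced) or "reml"

    @property
    def top_accession(self) -> str:
        return str(self.predictions["accession"][
            self.predictions["blup_d"].idxmax()])

    @property
    def bottom_accession(self) -> str:
        return str(self.predictions["accession"][
            self.predictions["blup_d"].idxmin()])


def _anova_components(values: np.ndarray) -> tuple[float, float]:
    """Balanced two-way (accession × rep, no interaction) mean squares."""
    n, r = values.shape
    grand = values.mean()
    acc_means = values.mean(axis=1)
    rep_means = values.mean(axis=0)
    ss_acc = r * ((acc_means - grand) ** 2).sum()
    ss_rep = n * ((rep_means - grand) ** 2).sum()
    ss_tot = ((values - grand) ** 2).sum()
    ss_res = ss_tot - ss_acc - ss_rep
    ms_acc = ss_acc / (n - 1)
    ms_res = max(ss_res, 0.0) / ((n - 1) * (r - 1))
    sigma2_e = ms_res
    sigma2_g = (ms_acc - ms_res) / r
    if sigma2_g < 0:
        warnings.warn("negative accession variance estimate truncated to 0",
                      stacklevel=3)
        sigma2_g = 0.0
    return sigma2_g, sigma2_e


def _reml_components(long: pd.DataFrame) -> tuple[float, float, pd.Series]:
    import statsmodels.formula.api as smf
    fit = smf.mixedlm("D ~ C(biorep)", long, groups=long["accession"]).fit(
        reml=True, method="lbfgs")
    sigma2_g = float(fit.cov_re.iloc[0, 0])
    sigma2_e = float(fit.scale)
    re = pd.Series({k: float(v.iloc[0]) for k, v in fit.random_effects.items()})
    return sigma2_g, sigma2_e, re


def fit_blup(d_table: pd.DataFrame) -> BlupResult:
    """BLUP-adjusted D per accession from an accession × replicate table.

    ``d_table`` has accession ids as index and one column per biological
    replicate.  A fully observed (balanced) table uses the closed-form
    ANOVA path; tables with missing cells use REML.
    """
    if d_table.shape[1] < 2:
        raise ValueError("need at least two biological replicates")
    values = d_table.to_numpy(dtype=float)
    n, r = values.shape
    balanced = np.isfinite(values).all()

    if balanced:
        sigma2_g, sigma2_e = _anova_components(values)
        h2 = sigma2_g / (sigma2_g + sigma2_e / r) if (sigma2_g + sigma2_e) > 0 else 0.0
        grand = float(values.mean())
        raw_dev = values.mean(axis=1) - grand
        blup_dev = h2 * raw_dev
        method = "anova"
    else:
        long = d_table.reset_index(names="accession").melt(
            id_vars="accession", var_name="biorep", value_name="D").dropna()
        sigma2_g, sigma2_e, re = _reml_components(long)
        h2 = sigma2_g / (sigma2_g + sigma2_e / r) if (sigma2_g + sigma2_e) > 0 else 0.0
        grand = float(long["D"].mean())
        raw_dev = d_table.mean(axis=1).to_numpy() - grand
        blup_dev = re.reindex(d_table.index).to_numpy()
        method = "reml"

    pred = pd.DataFrame({"accession": d_table.index})
    for j, col in enumerate(d_table.columns):
        pred[f"D_{col}"] = values[:, j]
    pred["raw_mean_d"] = d_table.mean(axis=1).to_numpy()
    pred["blup_d"] = grand + blup_dev
    best = int(np.argmax(pred["blup_d"].to_numpy()))
    worst = int(np.argmin(pred["blup_d"].to_numpy()))
    pred["flag"] = ""
    pred.loc[best, "flag"] = "top"
    pred.loc[worst, "flag"] = "bottom"
    return BlupResult(predictions=pred, sigma2_g=sigma2_g, sigma2_e=sigma2_e,
                      repeatability=h2, grand_mean=grand, method=method)


def prediction_error(blup_predicted, observed: pd.DataFrame,
                     against: str = "per_rep") -> float:
    """Mean relative prediction error, percent.

    ``per_rep`` (default) averages 100·|obs − pred|/obs over every
    (accession, replicate) cell; ``rep_mean`` compares against each
    accession's replicate-mean D instead.  Non-positive observations
    are excluded.
    """
    pred = pd.Series(blup_predicted, dtype=float)
    if against == "rep_mean":
        obs = observed.mean(axis=1)
        errs = (100.0 * (obs - pred).abs() / obs)[obs > 0]
    elif against == "per_rep":
        errs_cols = []
        for col in observed.columns:
            obs = observed[col]
            errs_cols.append((100.0 * (obs - pred).abs() / obs)[obs > 0])
        errs = pd.concat(errs_cols)
    else:
        raise ValueError(f"unknown comparison target {against!r}")
    if errs.empty:
        raise ValueError("no positive observed values to compare against")
    return float(errs.mean())
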