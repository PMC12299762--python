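"""Comprehensive drought-tolerance scores: D, WDC, CDC and Deng GRA.

Three composite scores rank the accessions:

* **D** — fuzzy-membership evaluation: each retained PCA component
  score is min–max rescaled to [0, 1] across accessions (the linear
  membership function μ) and the memberships are combined with the
  eigenvalue-share factor weights, D = Σ μ(x_i)·ω_i.
* **CDC** — comprehensive drought coefficient, the plain mean of an
  accession's eight DCs.
* **WDC** — weighted drought coefficient: each DC column's gray
  relational degree γ against the D reference (Deng's method) is
  normalized into weights ω_i(γ) = γ_i/Σγ_i, and WDC = Σ DC_i·ω_i(γ).

Gray relational analysis follows Deng's formulation: sequences are
normalized (min–max by default), per-element absolute deviations Δ from
the reference are formed, and the relational coefficient is
ξ(k) = (Δmin + ρ·Δmax)/(Δ(k) + ρ·Δmax), with Δmin/Δmax taken over all
comparison sequences and elements (the two-level extrema) and
distinguishing coefficient ρ = 0.5 by default; γ is the mean ξ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pca import PCAResult, run_pca


@dataclass(frozen=True)
class GRAResult:
    coefficients: pd.DataFrame  # ξ per element, comparisons as columns
    degrees: pd.Series          # γ per comparison sequence
    rho: float
    normalization: str

    def ranks(self) -> pd.Series:
        """Descending rank of γ; ties broken by column order."""
        order = np.lexsort((np.arange(len(self.degrees)),
                            -self.degrees.to_numpy()))
        ranks = pd.Series(0, index=self.degrees.index, dtype=int)
        ranks.iloc[order] = np.arange(1, len(self.degrees) + 1)
        return ranks


@dataclass(frozen=True)
class EvaluationScores:
    scores: pd.DataFrame        # accession × {D, WDC, CDC}
    membership: pd.DataFrame    # μ of each retained component
    pca_weights: np.ndarray     # ω_i (factor weights), sums to 1
    gra_weights: pd.Series      # ω_i(γ) per DC column, sums to 1
    gra_degrees: pd.Series      # γ of each DC column vs the D reference
    pca: PCAResult


def membership(scores: pd.DataFrame) -> pd.DataFrame:
    """Column-wise linear membership μ(x) = (x − min)/(max − min)."""
    lo, hi = scores.min(), scores.max()
    span = hi - lo
    if (span == 0).any():
        const = list(span.index[span == 0])
        raise ValueError(f"membership undefined for constant columns {const}")
    return (scores - lo) / span


def d_value(mu: pd.DataFrame, weights) -> pd.Series:
    """Weighted membership sum D = Σ μ(x_i)·ω_i ∈ [0, 1]."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (mu.shape[1],):
        raise ValueError(
            f"weight length {w.shape} does not match {mu.shape[1]} components")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    out = pd.Series(mu.to_numpy() @ w, index=mu.index, name="D")
    return out


def cdc(dc: pd.DataFrame) -> pd.Series:
    """Comprehensive drought coefficient: row mean of the DCs.

    Rows with missing entries yield NaN (flagged missing, not imputed).
    """
    out = dc.mean(axis=1, skipna=False)
    out.name = "CDC"
    return out


def _normalize(seq: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return seq
    if how == "minmax":
        lo, hi = seq.min(), seq.max()
        if hi == lo:
            return np.zeros_like(seq)
        return (seq - lo) / (hi - lo)
    raise ValueError(f"unknown normalization {how!r}")


def gray_relational_analysis(reference, comparisons: pd.DataFrame,
                             rho: float = 0.5,
                             normalization: str = "minmax",
                             delta_scope: str = "global") -> GRAResult:
    """Deng relational coefficients and degrees of comparison sequences.

    ``delta_scope`` controls where Δmin/Δmax are taken: ``global`` (the
    standard two-level extrema over every comparison and element) or
    ``per_comparison`` (each sequence against its own extrema).
    """
    ref = np.asarray(reference, dtype=float)
    if not 0.0 < rho <= 1.0:
        raise ValueError("distinguishing coefficient rho must lie in (0, 1]")
    if len(ref) < 2:
        raise ValueError("sequences must have at least two elements")
    if len(comparisons) != len(ref):
        raise ValueError("reference and comparison lengths differ")
    ref_n = _normalize(ref, normalization)
    deltas = {}
    for col in comparisons:
        comp_n = _normalize(comparisons[col].to_numpy(dtype=float),
                            normalization)
        deltas[col] = np.abs(ref_n - comp_n)
    delta = pd.DataFrame(deltas, index=comparisons.index)

    if delta_scope == "global":
        dmin, dmax = delta.to_numpy().min(), delta.to_numpy().max()
        dmin = np.full(delta.shape[1], dmin)
        dmax = np.full(delta.shape[1], dmax)
    elif delta_scope == "per_comparison":
        dmin, dmax = delta.min().to_numpy(), delta.max().to_numpy()
    else:
        raise ValueError(f"unknown delta_scope {delta_scope!r}")

    xi = {}
    for j, col in enumerate(delta.columns):
        if dmax[j] == 0:  # degenerate: every comparison equals the reference
            xi[col] = np.ones(len(ref))
        else:
            xi[col] = (dmin[j] + rho * dmax[j]) / (delta[col].to_numpy()
                                                   + rho * dmax[j])
    coeff = pd.DataFrame(xi, index=comparisons.index)
    degrees = coeff.mean()
    degrees.name = "gamma"
    return GRAResult(coefficients=coeff, degrees=degrees, rho=rho,
                     normalization=normalization)


def gray_relational_degree(reference, comparison, rho: float = 0.5,
                           normalization: str = "minmax") -> float:
    """γ of a single comparison sequence against the reference."""
    comp = pd.DataFrame({"x": np.asarray(comparison, dtype=float)})
    return float(gray_relational_analysis(
        reference, comp, rho=rho, normalization=normalization).degrees["x"])


def gra_weights(degrees) -> pd.Series:
    """ω_i(γ) = γ_i / Σγ_i; requires strictly positive degrees."""
    g = pd.Series(degrees, dtype=float)
    if (g <= 0).any():
        raise ValueError("relational degrees must be positive")
    out = g / g.sum()
    out.name = "weight"
    return out


def wdc(dc: pd.DataFrame, weights) -> pd.Series:
    """Weighted drought coefficient WDC = Σ DC_i·ω_i(γ) per accession."""
    w = pd.Series(weights, dtype=float)
    if list(w.index) != list(dc.columns):
        w = pd.Series(np.asarray(weights, dtype=float), index=dc.columns)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    out = (dc * w).sum(axis=1, skipna=False)
    out.name = "WDC"
    return out


def evaluate(dc: pd.DataFrame, rho: float = 0.5,
             normalization: str = "minmax", delta_scope: str = "global",
             retain: str = "fixed", k: int = 3) -> EvaluationScores:
    """Full evaluation of one biological replicate's DC matrix."""
    complete = dc.dropna()
    pca_res = run_pca(complete, retain=retain, k=k)
    mu = membership(pca_res.scores)
    d = d_value(mu, pca_res.factor_weights)
    gra = gray_relational_analysis(d, complete, rho=rho,
                                   normalization=normalization,
                                   delta_scope=delta_scope)
    w_gamma = gra_weights(gra.degrees)
    scores = pd.DataFrame({"D": d, "WDC": wdc(complete, w_gamma),
                           "CDC": cdc(complete)})
    return EvaluationScores(scores=scores, membership=mu,
                            pca_weights=pca_res.factor_weights,
                            gra_weights=w_gamma, gra_degrees=gra.degrees,
                            pca=pca_res)


def indicator_ranking(dc: pd.DataFrame, scores: pd.DataFrame,
                      rho: float = 0.5, normalization: str = "minmax",
                      delta_scope: str = "global") -> pd.DataFrame:
    """Gray-relational sensitivity ranking of the eight DC indicators.

    For each composite score (D, WDC, CDC) as the reference sequence,
    reports every DC column's relational degree and its descending
    rank — the layout of a screen's indicator-ranking table.
    """
    complete = dc.dropna()
    out = pd.DataFrame(index=dc.columns)
    for name in scores.columns:
        gra = gray_relational_analysis(
            scores.loc[complete.index, name], complete, rho=rho,
            normalization=normalization, delta_scope=delta_scope)
        out[f"{name}_degree"] = gra.degrees
        out[f"{name}_rank"] = gra.ranks()
    out.index.name = "indicator"
    return out
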