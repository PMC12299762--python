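"""Correlation-matrix PCA of the DC matrix and eigenvalue-share weights.

The eight drought-tolerance coefficients are standardized (zero mean,
unit sample variance), the correlation matrix is eigen-decomposed, and
the leading components become composite drought-tolerance indicators.
Each retained component's factor weight is its share of the retained
eigenvalue mass, ω_i = λ_i / Σλ_i — equivalently its contribution ratio
P_i over the retained components' ΣP_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray        # all p eigenvalues, descending
    contribution_ratio: np.ndarray  # percent of total variance, per component
    cumulative_ratio: np.ndarray   # running sum of contribution ratios
    n_retained: int
    factor_weights: np.ndarray     # ω over retained components, sums to 1
    loadings: pd.DataFrame         # unit eigenvectors, traits × retained PCs
    scores: pd.DataFrame           # accessions × retained PCs

    @property
    def retained_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[: self.n_retained]


def factor_weights(eigenvalues) -> np.ndarray:
    """ω_i = λ_i / Σλ_i over the retained components; sums to one."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("need at least one retained component")
    return lam / lam.sum()


def _n_retained(eigenvalues: np.ndarray, retain: str, k: int,
                cum_threshold: float) -> int:
    if retain == "fixed":
        return int(k)
    if retain == "cumulative":
        share = 100.0 * np.cumsum(eigenvalues) / eigenvalues.sum()
        return int(np.searchsorted(share, cum_threshold) + 1)
    if retain == "kaiser":
        return max(int((eigenvalues > 1.0).sum()), 1)
    raise ValueError(f"unknown retention policy {retain!r}")


def run_pca(dc: pd.DataFrame, retain: str = "fixed", k: int = 3,
            cum_threshold: float = 85.0) -> PCAResult:
    """PCA of a complete DC matrix.

    Rows with any missing value are rejected (the screen design is
    complete; partial projection is deliberately not offered).  The sign
    of each eigenvector is fixed so its largest-magnitude loading is
    positive, making component scores reproducible.
    """
    if dc.isna().any().any():
        bad = list(dc.index[dc.isna().any(axis=1)])
        raise ValueError(f"DC matrix has missing values in rows {bad[:5]}")
    n, p = dc.shape
    if n < p + 1:
        raise ValueError(f"need more rows ({n}) than traits ({p}) for PCA")
    sd = dc.std(ddof=1)
    degenerate = list(sd.index[(sd == 0) | ~np.isfinite(sd)])
    if degenerate:
        raise ValueError(f"constant or degenerate columns: {degenerate}")
    corr = dc.corr().to_numpy()
    if np.linalg.matrix_rank(corr) < p:
        dup = [c for i, c in enumerate(dc.columns)
               for j in range(i) if np.isclose(abs(corr[i, j]), 1.0)]
        raise ValueError(
            f"rank-deficient correlation matrix; duplicated columns: {dup}")

    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam = np.clip(lam, 0.0, None)
    # Deterministic sign: largest-|loading| entry of each vector positive.
    for j in range(p):
        i = np.argmax(np.abs(vec[:, j]))
        if vec[i, j] < 0:
            vec[:, j] = -vec[:, j]

    contribution = 100.0 * lam / lam.sum()
    cumulative = np.cumsum(contribution)
    m = _n_retained(lam, retain, k, cum_threshold)
    m = min(max(m, 1), p)

    z = (dc - dc.mean()) / sd
    scores = pd.DataFrame(z.to_numpy() @ vec[:, :m], index=dc.index,
                          columns=[f"PC{i + 1}" for i in range(m)])
    loadings = pd.DataFrame(vec[:, :m], index=dc.columns,
                            columns=scores.columns)
    return PCAResult(eigenvalues=lam, contribution_ratio=contribution,
                     cumulative_ratio=cumulative, n_retained=m,
                     factor_weights=factor_weights(lam[:m]),
                     loadings=loadings, scores=scores)


def pca_table(result: PCAResult) -> pd.DataFrame:
    """Report layout: eigenvalue, contribution, cumulative, weight, loadings."""
    m = result.n_retained
    head = pd.DataFrame(
        [result.retained_eigenvalues,
         result.contribution_ratio[:m],
         result.cumulative_ratio[:m],
         result.factor_weights],
        index=["eigenvalue", "contribution_ratio_pct",
               "cumulative_ratio_pct", "factor_weight"],
        columns=result.loadings.columns)
    return pd.concat([head, result.loadings])
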