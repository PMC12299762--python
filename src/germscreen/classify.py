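"""Five-grade drought-resistance classification of D-values.

Accessions are clustered on their D-value by agglomerative hierarchical
clustering with Euclidean distance and between-groups (unweighted
average, UPGMA) linkage; the tree is cut at k clusters and clusters are
relabeled by descending mean D into ordered grades I (strongly
drought-resistant) … V (strongly sensitive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

GRADE_LABELS = (
    "strongly drought-resistant",
    "drought-resistant",
    "medium",
    "sensitive",
    "strongly sensitive",
)

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass(frozen=True)
class GradeAssignment:
    assignments: pd.DataFrame  # accession, D, cluster, grade, grade_label
    summary: pd.DataFrame      # grade, count, percent, mean_d
    linkage: np.ndarray        # scipy linkage matrix (sorted-input order)


def grade_percentages(counts, n: int | None = None) -> list[float]:
    """Percent of accessions per grade, rounded to one decimal."""
    counts = np.asarray(counts, dtype=float)
    total = float(n if n is not None else counts.sum())
    return [round(100.0 * c / total, 1) for c in counts]


def classify_grades(d, k: int = 5, labels=None) -> GradeAssignment:
    """Cluster D-values into k ordered grades.

    Clustering runs on the values sorted ascending (average-linkage
    clusters of one-dimensional data are contiguous in sorted order), so
    the partition is independent of input order; assignments are mapped
    back to the original accessions.  Accepts a Series (index = accession
    ids) or a 1-D/2-D array; multivariate input is clustered as-is
    without the sorted-order canonicalization.
    """
    if isinstance(d, pd.Series):
        index = d.index
        values = d.to_numpy(dtype=float)[:, None]
    else:
        values = np.asarray(d, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        index = pd.RangeIndex(len(values))
    if not np.isfinite(values).all():
        raise ValueError("D values must be finite")
    n = len(values)
    if n < k:
        raise ValueError(f"cannot form {k} grades from {n} accessions")
    if labels is None:
        labels = GRADE_LABELS if k == 5 else tuple(
            f"grade {_ROMAN[i]}" for i in range(k))
    if len(labels) != k:
        raise ValueError("label count must equal k")

    univariate = values.shape[1] == 1
    if univariate:
        order = np.lexsort((np.arange(n), values[:, 0]))
        work = values[order]
    else:
        order = np.arange(n)
        work = values
    link = hierarchy.linkage(work, method="average", metric="euclidean")
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    if len(np.unique(flat)) < k:
        raise ValueError(
            f"only {len(np.unique(flat))} distinct clusters formed; "
            f"too few distinct merge heights — use a smaller k")

    cluster = np.empty(n, dtype=int)
    cluster[order] = flat
    d_series = pd.Series(values.mean(axis=1), index=index, name="D")
    means = d_series.groupby(cluster).mean()
    # Grade I = highest mean D.
    rank_of = {cl: r for r, cl in enumerate(
        means.sort_values(ascending=False).index)}
    grade_idx = np.array([rank_of[c] for c in cluster])

    assignments = pd.DataFrame({
        "accession": index,
        "D": d_series.to_numpy(),
        "cluster": cluster,
        "grade": [_ROMAN[g] for g in grade_idx],
        "grade_label": [labels[g] for g in grade_idx],
    })
    counts = np.bincount(grade_idx, minlength=k)
    summary = pd.DataFrame({
        "grade": [_ROMAN[i] for i in range(k)],
        "label": list(labels),
        "count": counts,
        "percent": grade_percentages(counts, n),
        "mean_d": [d_series.to_numpy()[grade_idx == i].mean() for i in range(k)],
    })
    return GradeAssignment(assignments=assignments, summary=summary,
                           linkage=link)


def dendrogram_text(link: np.ndarray, leaf_names=None) -> str:
    """Newick-style nested-text export of the merge tree."""
    n = link.shape[0] + 1
    if leaf_names is None:
        leaf_names = [str(i) for i in range(n)]
    nodes = {i: str(leaf_names[i]) for i in range(n)}
    for i, (a, b, height, _) in enumerate(link):
        nodes[n + i] = f"({nodes.pop(int(a))},{nodes.pop(int(b))}):{height:.6g}"
    return next(iter(nodes.values())) + ";"
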