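"""Normalization, clustering-based sample exclusion, differential expression.

``normalize_2z8`` rescales log2 expression to mean 8 and standard deviation 2
("2Z + 8"): the upward shift keeps all values positive while preserving every
correlation and linkage statistic (both are affine-invariant).  The default
axis rescales each gene row; ``axis="samples"`` rescales each array instead,
which is the convention under which per-gene mean-expression gates (> 7, >= 8)
remain informative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, ValidationError

__all__ = [
    "normalize_2z8",
    "exclude_outlier_samples",
    "differential_expression",
    "bh_adjust",
]

_TINY_P = np.nextafter(0.0, 1.0)


def normalize_2z8(matrix: ExpressionMatrix, axis: str = "genes") -> ExpressionMatrix:
    """Return a copy rescaled to mean 8, sd 2 along ``axis``.

    Z-scores use the sample (n-1) standard deviation.  Constant rows (or
    columns) have no defined z-score and map to the target mean 8, which
    keeps the matrix shape and alignment intact.
    """
    if axis not in ("genes", "samples"):
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    vals = matrix.values.to_numpy(dtype=float)
    ax = 1 if axis == "genes" else 0
    n = vals.shape[ax]
    if n < 2:
        raise ValidationError(f"2Z+8 normalization needs at least 2 {axis}")
    mean = vals.mean(axis=ax, keepdims=True)
    sd = vals.std(axis=ax, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z = np.where(sd == 0, 0.0, z)
    out = pd.DataFrame(2.0 * z + 8.0, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(out, matrix.gene_annotation, matrix.sample_group)


def exclude_outlier_samples(
    matrix: ExpressionMatrix,
    labels: pd.Series | None = None,
    linkage_method: str = "average",
) -> tuple[list[str], list[str]]:
    """Hierarchical-clustering sample exclusion before differential expression.

    Samples are clustered on Euclidean distance between expression columns
    (agglomerative, ``linkage_method`` linkage), the tree is cut into two
    clusters, each cluster takes the majority group label, and samples whose
    own label disagrees with their cluster's majority are excluded.

    Returns ``(retained_sample_ids, excluded_sample_ids)``.
    """
    labels = _resolve_labels(matrix, labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"exactly two group labels required, found {groups}")
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    dist = pdist(X, metric="euclidean")
    if np.all(dist == 0):
        raise ValidationError(
            "all samples identical: no two-cluster structure (zero-distance ties)"
        )
    Z = linkage(dist, method=linkage_method)
    assignment = fcluster(Z, t=2, criterion="maxclust")
    if len(np.unique(assignment)) < 2:
        raise ValidationError("clustering did not produce two clusters")
    samples = list(matrix.values.columns)
    majority: dict[int, str] = {}
    for cl in np.unique(assignment):
        members = labels.iloc[np.flatnonzero(assignment == cl)]
        counts = members.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            raise ValidationError(
                f"cluster {cl} has a tied majority label ({dict(counts)}); manual review needed"
            )
        majority[int(cl)] = counts.index[0]
    retained, excluded = [], []
    for i, s in enumerate(samples):
        (excluded if labels.iloc[i] != majority[int(assignment[i])] else retained).append(s)
    return retained, excluded


def differential_expression(
    matrix: ExpressionMatrix,
    labels: pd.Series | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Welch t-test with Benjamini-Hochberg correction.

    ``diff`` is mean(second group) - mean(first group) on the log2 scale,
    with groups in sorted label order.  Genes identical across both groups
    get ``t = 0, p = 1``.  Returns columns
    ``gene, diff, t, p, fdr, significant``.
    """
    labels = _resolve_labels(matrix, labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"exactly two group labels required, found {groups}")
    a = matrix.values.loc[:, labels[labels == groups[0]].index].to_numpy(dtype=float)
    b = matrix.values.loc[:, labels[labels == groups[1]].index].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each group needs at least 2 samples for a Welch t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    diff = b.mean(axis=1) - a.mean(axis=1)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    same = zero_var & (diff == 0)
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    apart = zero_var & (diff != 0)
    t = np.where(apart, np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(apart, _TINY_P, p)
    adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": matrix.values.index,
            "diff": diff,
            "t": t,
            "p": p,
            "fdr": adj,
            "significant": adj < fdr,
        }
    ).reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def _resolve_labels(matrix: ExpressionMatrix, labels: pd.Series | None) -> pd.Series:
    if labels is None:
        labels = matrix.sample_group
    if labels is None:
        raise ValidationError("no sample group labels available")
    labels = labels.reindex(matrix.values.columns)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:5]
        raise ValidationError(f"samples without group label: {missing}")
    return labels.astype(str)
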