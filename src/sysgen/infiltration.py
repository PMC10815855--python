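"""ssGSEA immune-infiltration scoring and group comparison.

Cell-type abundance in a bulk sample is summarised by a single-sample gene
set enrichment score (ssGSEA, Barbie-style): genes are ranked by expression
within the sample (descending; the highest-expressed gene carries rank
weight N), and the score is the integrated difference between the weighted
running fraction of signature genes encountered and the uniform running
fraction of non-signature genes:

    ES = sum_i [ P_in(i) - P_out(i) ],
    P_in(i)  = sum_{j <= i, j in S} w_j^alpha / sum_{j in S} w_j^alpha,
    P_out(i) = #(j <= i, j not in S) / (N - K),

with w_j the descending rank weight and alpha = 0.25 by default.  Scores
depend on expression only through within-sample ranks, so they are invariant
under any strictly increasing transform of a sample's values.  Differential
infiltration between two sample groups uses the two-sided Wilcoxon rank-sum
test (exact for small tie-free samples, normal approximation with tie
correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import pearson_with_p
from .types import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError

__all__ = [
    "InfiltrationScores",
    "ssgsea_score",
    "infiltration_matrix",
    "differential_infiltration",
    "correlate_genes_with_infiltration",
]


@dataclass
class InfiltrationScores:
    """Samples x cell types ssGSEA scores with optional group labels."""

    scores: pd.DataFrame
    sample_group: pd.Series | None = None
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("infiltration scores must be finite")
        if self.sample_group is not None:
            self.sample_group = self.sample_group.reindex(self.scores.index)
            if self.sample_group.isna().any():
                raise ValidationError("every scored sample needs a group label")

    def minmax_scaled(self) -> pd.DataFrame:
        """Optional per-cell-type min-max rescaling of the raw scores to [0, 1]."""
        lo = self.scores.min(axis=0)
        span = self.scores.max(axis=0) - lo
        span = span.replace(0, 1.0)
        return (self.scores - lo) / span


def ssgsea_score(sample_expression: pd.Series, gene_set: GeneSet | set | list,
                 alpha: float = 0.25) -> float:
    """ssGSEA enrichment score of one gene set in one sample.

    ``sample_expression`` maps gene id -> expression value.  Ties in
    expression take the average rank weight; tied genes are ordered by gene
    id for determinism.  Raises if no set member is measured, or if the set
    covers the whole measured universe (the complement running sum is then
    undefined).
    """
    if not isinstance(sample_expression, pd.Series):
        raise ValidationError("sample_expression must be a gene-indexed Series")
    name = gene_set.name if isinstance(gene_set, GeneSet) else ""
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    values = sample_expression.astype(float)
    N = len(values)
    in_set_all = values.index.isin(members)
    K = int(in_set_all.sum())
    if K == 0:
        raise ValidationError(f"no member of gene set {name!r} is measured in the sample")
    if K == N:
        raise ValidationError(f"gene set {name!r} covers every measured gene")
    # average-rank weights: highest-expressed gene carries weight N
    ranks = stats.rankdata(values.to_numpy(), method="average")
    order = np.lexsort((values.index.to_numpy(), -values.to_numpy()))  # descending, ties by id
    w = np.abs(ranks[order]) ** alpha
    in_set = in_set_all[order]
    p_in = np.cumsum(np.where(in_set, w, 0.0)) / np.sum(w[in_set])
    p_out = np.cumsum(~in_set) / (N - K)
    return float(np.sum(p_in - p_out))


def infiltration_matrix(matrix: ExpressionMatrix, signatures: GeneSetCollection,
                        alpha: float = 0.25) -> InfiltrationScores:
    """ssGSEA score for every sample x signature set."""
    out = pd.DataFrame(
        {
            name: [
                ssgsea_score(matrix.values[s], gs, alpha) for s in matrix.values.columns
            ]
            for name, gs in signatures.items()
        },
        index=pd.Index(matrix.values.columns, name="sample"),
    )
    return InfiltrationScores(out, matrix.sample_group, alpha)


def differential_infiltration(scores: InfiltrationScores, p_threshold: float = 0.05,
                              test: str = "wilcoxon") -> pd.DataFrame:
    """Group-wise comparison of infiltration scores per cell type.

    Uses the two-sided Wilcoxon rank-sum test by default (exact when the
    combined sample size is <= 20 and there are no ties); ``test="ttest"``
    switches to Welch's t.  Returns per-cell-type group medians, p-value and
    a significance flag at ``p_threshold``.
    """
    if scores.sample_group is None:
        raise ValidationError("differential infiltration requires sample group labels")
    groups = sorted(scores.sample_group.astype(str).unique())
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups required, found {groups}")
    ga = scores.scores[scores.sample_group.astype(str) == groups[0]]
    gb = scores.scores[scores.sample_group.astype(str) == groups[1]]
    if len(ga) < 3 or len(gb) < 3:
        raise ValidationError("each group needs at least 3 samples")
    rows = []
    for cell in scores.scores.columns:
        a = ga[cell].to_numpy(dtype=float)
        b = gb[cell].to_numpy(dtype=float)
        p = _two_sample_p(a, b, test)
        rows.append(
            {
                "cell_type": cell,
                f"median_{groups[0]}": float(np.median(a)),
                f"median_{groups[1]}": float(np.median(b)),
                "p": p,
                "significant": p < p_threshold,
            }
        )
    return pd.DataFrame(rows)


def _two_sample_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == "ttest":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test != "wilcoxon":
        raise ValueError(f"unknown test {test!r}")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue))


def correlate_genes_with_infiltration(
    matrix: ExpressionMatrix,
    scores: InfiltrationScores,
    gene_list: list[str],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of gene expression against per-sample cell scores.

    Returns a tidy genes x cell-types table with columns
    ``gene, cell_type, r, p, n, significant``.
    """
    missing = [g for g in gene_list if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"genes not in expression matrix: {missing[:5]}")
    shared = [s for s in matrix.sample_ids if s in scores.scores.index]
    if not shared:
        raise ValidationError("no overlapping samples between expression and scores")
    rows = []
    for gene in gene_list:
        x = matrix.values.loc[gene, shared].to_numpy(dtype=float)
        for cell in scores.scores.columns:
            y = scores.scores.loc[shared, cell].to_numpy(dtype=float)
            r, p, n = pearson_with_p(x, y)
            rows.append(
                {"gene": gene, "cell_type": cell, "r": r, "p": p, "n": n,
                 "significant": p < p_threshold}
            )
    return pd.DataFrame(rows)
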