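"""Pearson correlation screens.

All correlations are pairwise-complete (missing phenotype values drop only
the affected pairs, never whole rows) and report the two-sided p-value from
t = r * sqrt((n - 2) / (1 - r^2)) against Student's t with n - 2 degrees of
freedom.  The transcriptome screen filters partners on nominal significance
and a mean-expression gate (> 7 by default, the murine convention); the
human-style screen additionally requires |r| >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, TraitTable, ValidationError

__all__ = [
    "pearson_with_p",
    "correlate_focal_gene",
    "correlate_genes_with_traits",
    "fold_difference",
    "FoldDifference",
]

_TINY_P = np.nextafter(0.0, 1.0)


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided t-test p-value on pairwise-complete pairs.

    Returns ``(r, p, n)`` where n is the pairwise-complete count.  |r| = 1
    yields a p-value clamped to the smallest positive float rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(mask.sum())
    if n < 3:
        raise ValidationError(f"need at least 3 pairwise-complete observations, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx**2).sum())
    sy = np.sqrt((dy**2).sum())
    if sx == 0 or sy == 0:
        raise ValidationError("undefined correlation: constant vector")
    r = float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))
    p = _p_from_r(r, n)
    return r, p, n


def _p_from_r(r: float | np.ndarray, n: int | np.ndarray) -> float | np.ndarray:
    scalar = np.ndim(r) == 0
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, _TINY_P, p)
    p = np.clip(p, _TINY_P, 1.0)
    return float(p) if scalar else p


def correlate_focal_gene(
    matrix: ExpressionMatrix,
    focal_gene: str,
    p_threshold: float = 0.05,
    min_mean: float = 7.0,
    r_threshold: float = 0.0,
) -> pd.DataFrame:
    """Correlate every other gene with the focal gene and apply the screen.

    ``passes_filter`` is true iff p < ``p_threshold`` AND the partner's mean
    expression is strictly greater than ``min_mean`` AND |r| >= ``r_threshold``
    (set ``r_threshold=0.5`` for the human-style screen).  Constant partner
    genes get ``r = NaN`` and never pass.  The focal gene itself is excluded.
    """
    if focal_gene not in matrix.values.index:
        raise ValidationError(f"focal gene {focal_gene!r} not in expression matrix")
    vals = matrix.values
    focal = vals.loc[focal_gene].to_numpy(dtype=float)
    partners = vals.index[vals.index != focal_gene]
    X = vals.loc[partners].to_numpy(dtype=float)

    if np.isfinite(X).all() and np.isfinite(focal).all():
        n = len(focal)
        if n < 3:
            raise ValidationError("need at least 3 samples")
        dy = focal - focal.mean()
        sy = np.sqrt((dy**2).sum())
        if sy == 0:
            raise ValidationError("undefined correlation: focal gene is constant")
        dX = X - X.mean(axis=1, keepdims=True)
        sX = np.sqrt((dX**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip((dX @ dy) / (sX * sy), -1.0, 1.0)
        r = np.where(sX == 0, np.nan, r)
        ok = np.isfinite(r)
        p = np.full_like(r, np.nan)
        p[ok] = _p_from_r(r[ok], n)
        ns = np.full(len(partners), n)
    else:
        r = np.empty(len(partners))
        p = np.empty(len(partners))
        ns = np.empty(len(partners), dtype=int)
        for i, g in enumerate(partners):
            try:
                r[i], p[i], ns[i] = pearson_with_p(X[i], focal)
            except ValidationError:
                r[i], p[i], ns[i] = np.nan, np.nan, 0

    mean_expr = np.nanmean(X, axis=1)
    passes = (
        np.isfinite(p)
        & (p < p_threshold)
        & (mean_expr > min_mean)
        & (np.abs(np.nan_to_num(r)) >= r_threshold)
    )
    return pd.DataFrame(
        {
            "partner": partners,
            "r": r,
            "p": p,
            "n": ns,
            "mean_expression": mean_expr,
            "passes_filter": passes,
        }
    ).reset_index(drop=True)


def correlate_genes_with_traits(
    matrix: ExpressionMatrix,
    traits: TraitTable,
    gene_list: list[str] | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of genes against trait values.

    Strains are matched by sample/strain id; a missing trait value reduces n
    for that (gene, trait) pair only.  Returns a tidy table with columns
    ``gene, trait, r, p, n, significant``.
    """
    genes = list(gene_list) if gene_list is not None else list(matrix.values.index)
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"genes not in expression matrix: {missing[:5]}")
    shared = [s for s in matrix.sample_ids if s in traits.values.index]
    if not shared:
        raise ValidationError("no overlapping strains between expression and traits")
    expr = matrix.values.loc[genes, shared]
    tvals = traits.values.loc[shared]
    rows = []
    for gene in genes:
        x = expr.loc[gene].to_numpy(dtype=float)
        for trait in tvals.columns:
            y = tvals[trait].to_numpy(dtype=float)
            try:
                r, p, n = pearson_with_p(x, y)
            except ValidationError:
                r, p, n = np.nan, np.nan, int((np.isfinite(x) & np.isfinite(y)).sum())
            rows.append(
                {"gene": gene, "trait": trait, "r": r, "p": p, "n": n,
                 "significant": bool(np.isfinite(p) and p < p_threshold)}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldDifference:
    min_id: str
    max_id: str
    min_value: float
    max_value: float
    fold: float


def fold_difference(values: pd.Series) -> FoldDifference:
    """Fold difference across strains from per-strain log2 means: 2**(max - min)."""
    values = values.dropna()
    if len(values) == 0:
        raise ValidationError("fold_difference needs at least one value")
    imin, imax = values.idxmin(), values.idxmax()
    lo, hi = float(values.min()), float(values.max())
    return FoldDifference(str(imin), str(imax), lo, hi, float(2.0 ** (hi - lo)))
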