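"""Weighted 0-10 candidate-regulator prioritization.

Genes inside a QTL support interval are scored on five parameters:
heart expression (mean >= 8 on the 2Z+8 scale: 1 point), a damaging coding
variant between the parental strains (1), cis-regulation of the gene's own
expression (1), significant correlation with the focal gene (2), and
functional evidence from curated databases (capped at 5; disease-causal
sources RGD and the GWAS Catalog weigh 2, other sources 1).  The maximum
total is 10 and genes scoring at least half of it (>= 5) are selected.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .correlation import pearson_with_p
from .eqtl import QtlPeak
from .types import (
    EVIDENCE_COLUMNS,
    ExpressionMatrix,
    ValidationError,
    chrom_sort_key,
    validate_evidence,
)

__all__ = [
    "ScoringWeights",
    "CandidateScore",
    "score_gene",
    "score_table",
    "select_candidates",
    "build_evidence",
    "load_published_candidate_evidence",
    "CODING_CONSEQUENCES",
]

#: Variant consequences that count as damaging coding variants.
CODING_CONSEQUENCES = frozenset(
    {
        "nonsynonymous",
        "non-synonymous",
        "nonsyn",
        "missense",
        "frameshift",
        "frame shift",
        "frame_shift",
        "stop gain",
        "stop_gained",
        "stop gained",
        "stop loss",
        "stop_lost",
        "stop lost",
    }
)


def _default_functional_weights() -> dict[str, int]:
    return {"RGD_causal": 2, "GWAS_catalog": 2, "MGI": 1, "IMPC": 1, "KEGG": 1, "Alliance": 1}


@dataclass(frozen=True)
class ScoringWeights:
    expression: int = 1
    variant: int = 1
    cis: int = 1
    correlation: int = 2
    functional: Mapping[str, int] = field(default_factory=_default_functional_weights)
    functional_cap: int = 5
    expression_gate: float = 8.0
    select_threshold: int = 5

    @property
    def max_total(self) -> int:
        return self.expression + self.variant + self.cis + self.correlation + self.functional_cap


@dataclass(frozen=True)
class CandidateScore:
    gene: str
    expression_score: int
    variant_score: int
    cis_score: int
    correlation_score: int
    functional_score: int
    total: int
    selected: bool


def score_gene(evidence: Mapping, weights: ScoringWeights = ScoringWeights()) -> CandidateScore:
    """Score one evidence row (a mapping or DataFrame row) under ``weights``."""
    mean_expr = evidence["mean_expression"]
    expr_ok = bool(np.isfinite(mean_expr) and mean_expr >= weights.expression_gate)
    e = weights.expression if expr_ok else 0
    v = weights.variant if bool(evidence["has_coding_variant"]) else 0
    c = weights.cis if bool(evidence["is_cis_regulated"]) else 0
    r = weights.correlation if bool(evidence["sig_corr_with_focal"]) else 0
    sources = evidence["functional_sources"]
    if isinstance(sources, str):
        sources = frozenset(s for s in sources.split(";") if s)
    unknown = set(sources) - set(weights.functional)
    if unknown:
        raise ValidationError(f"no weight configured for functional sources {sorted(unknown)}")
    f = min(weights.functional_cap, sum(weights.functional[s] for s in sources))
    total = e + v + c + r + f
    return CandidateScore(
        gene=str(evidence["gene"]),
        expression_score=e,
        variant_score=v,
        cis_score=c,
        correlation_score=r,
        functional_score=f,
        total=total,
        selected=total >= weights.select_threshold,
    )


def score_table(evidence: pd.DataFrame,
                weights: ScoringWeights = ScoringWeights()) -> pd.DataFrame:
    """Score every evidence row; carries chrom/pos columns when present."""
    evidence = validate_evidence(evidence)
    rows = []
    for _, row in evidence.iterrows():
        cs = score_gene(row, weights)
        rec = {
            "gene": cs.gene,
            "expression_score": cs.expression_score,
            "variant_score": cs.variant_score,
            "cis_score": cs.cis_score,
            "correlation_score": cs.correlation_score,
            "functional_score": cs.functional_score,
            "total": cs.total,
            "selected": cs.selected,
        }
        for extra in ("chrom", "pos_mb"):
            if extra in evidence.columns:
                rec[extra] = row[extra]
        rows.append(rec)
    columns = ["gene", "expression_score", "variant_score", "cis_score",
               "correlation_score", "functional_score", "total", "selected"]
    columns += [c for c in ("chrom", "pos_mb") if c in evidence.columns]
    return pd.DataFrame(rows, columns=columns)


def select_candidates(scores: pd.DataFrame, threshold: int = 5) -> pd.DataFrame:
    """Genes with total >= threshold, ranked by (total desc, genomic order).

    Sorting is stable: ties beyond (total, chromosome, position) preserve the
    input order.
    """
    if scores.empty:
        return scores.copy()
    out = scores[scores["total"] >= threshold].copy()
    by = ["_neg_total"]
    out["_neg_total"] = -out["total"]
    if "chrom" in out.columns:
        out["_chrom_key"] = [chrom_sort_key(c) for c in out["chrom"]]
        by.append("_chrom_key")
    if "pos_mb" in out.columns:
        by.append("pos_mb")
    out = (
        out.sort_values(by, kind="stable")
        .drop(columns=[c for c in ("_neg_total", "_chrom_key") if c in out.columns])
        .reset_index(drop=True)
    )
    out["selected"] = True
    return out


def build_evidence(
    interval_genes: list[str],
    expression: ExpressionMatrix,
    variant_table: pd.DataFrame | None,
    gene_peaks: Mapping[str, QtlPeak | str] | None,
    focal_correlations: pd.DataFrame | None,
    functional_table: pd.DataFrame | Mapping[str, set] | None,
    p_threshold: float = 0.05,
    focal_gene: str | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene evidence table for scoring.

    ``variant_table`` needs columns ``gene`` and ``consequence`` (only
    damaging coding consequences count; synonymous variants do not).
    ``gene_peaks`` maps gene -> classified :class:`QtlPeak` (its
    ``regulation`` label) or directly to ``"cis"``/``"trans"``.
    ``focal_correlations`` is the output of
    :func:`~sysgen.correlation.correlate_focal_gene`; if absent and
    ``focal_gene`` is given, correlations are computed on the fly.
    ``functional_table`` needs columns ``gene`` and ``source``.
    """
    import warnings

    variant_genes: set[str] = set()
    if variant_table is not None and len(variant_table):
        cons = variant_table["consequence"].astype(str).str.strip().str.lower()
        variant_genes = set(variant_table.loc[cons.isin(CODING_CONSEQUENCES), "gene"].astype(str))

    corr_p: dict[str, float] = {}
    if focal_correlations is not None:
        corr_p = dict(zip(focal_correlations["partner"].astype(str), focal_correlations["p"]))

    func_sources: dict[str, set[str]] = {}
    if isinstance(functional_table, pd.DataFrame):
        for _, row in functional_table.iterrows():
            func_sources.setdefault(str(row["gene"]), set()).add(str(row["source"]))
    elif functional_table is not None:
        func_sources = {g: set(s) for g, s in functional_table.items()}

    rows = []
    for gene in interval_genes:
        if gene in expression.values.index:
            mean_expr = float(expression.values.loc[gene].mean())
        else:
            warnings.warn(f"gene {gene!r} missing from expression matrix; gate set false",
                          stacklevel=2)
            mean_expr = float("nan")
        if gene in corr_p:
            p = corr_p[gene]
        elif focal_gene is not None and gene in expression.values.index:
            try:
                _, p, _ = pearson_with_p(
                    expression.values.loc[gene], expression.values.loc[focal_gene]
                )
            except ValidationError:
                p = float("nan")
        else:
            p = float("nan")
        regulation = None
        if gene_peaks is not None and gene in gene_peaks:
            pk = gene_peaks[gene]
            regulation = pk if isinstance(pk, str) else pk.regulation
        chrom, pos = (None, float("nan"))
        if expression.gene_annotation is not None and gene in expression.gene_annotation.index:
            chrom, pos = expression.gene_location(gene)
        rows.append(
            {
                "gene": gene,
                "chrom": chrom,
                "pos_mb": pos,
                "mean_expression": mean_expr,
                "has_coding_variant": gene in variant_genes,
                "is_cis_regulated": regulation == "cis",
                "sig_corr_with_focal": bool(np.isfinite(p) and p < p_threshold),
                "functional_sources": frozenset(func_sources.get(gene, ())),
            }
        )
    return validate_evidence(pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS)))


def load_published_candidate_evidence() -> pd.DataFrame:
    """The twelve published candidate-gene indicator rows for the Rpl3l
    trans-QTL support intervals (chromosomes 11 and 13), as an evidence table."""
    from . import io_formats

    path = resources.files("sysgen.data").joinpath("rpl3l_candidate_evidence.tsv")
    with resources.as_file(path) as p:
        return io_formats.read_evidence(p)
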