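"""Over-representation analysis (ORA) against a gene-set collection.

For a query of n genes drawn from a universe of N genes, the overlap k with
a set of K universe members is tested with the hypergeometric upper tail
P(X >= k); p-values are Benjamini-Hochberg adjusted across all tested sets.
The enrichment ratio is (k/n) / (K/N).  The default universe is every gene
measured on the platform (the rows of the expression matrix), overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .preprocess import bh_adjust
from .types import GeneSet, GeneSetCollection, ValidationError

__all__ = ["EnrichmentRow", "ora_hypergeometric", "enrich_collection"]

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    k: int  # overlap count
    n: int  # query size within universe
    K: int  # set size within universe
    N: int  # universe size
    p: float
    enrichment_ratio: float


def ora_hypergeometric(query, gene_set: GeneSet | set | list, universe) -> EnrichmentRow:
    """Hypergeometric upper-tail over-representation test for one set.

    Query genes outside the universe are dropped with a warning; duplicate
    query genes are counted once.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query_set = set(query)
    outside = query_set - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped", stacklevel=2
        )
    query_set &= universe
    if not query_set:
        raise ValidationError("no query genes inside the universe")
    name = gene_set.name if isinstance(gene_set, GeneSet) else ""
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    members &= universe
    if not members:
        raise ValidationError(f"gene set {name!r} has no members inside the universe")
    N, K, n = len(universe), len(members), len(query_set)
    k = len(query_set & members)
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = float(np.clip(p, _TINY_P, 1.0))
    ratio = (k / n) / (K / N)
    return EnrichmentRow(set_name=name, k=k, n=n, K=K, N=N, p=p, enrichment_ratio=ratio)


def enrich_collection(
    query,
    collection: GeneSetCollection,
    universe,
    fdr_threshold: float = 0.05,
    min_set: int = 3,
) -> pd.DataFrame:
    """ORA of a query list against every set in the collection.

    Sets with fewer than ``min_set`` members inside the universe are not
    tested.  Rows are BH-adjusted across all tested sets and sorted by
    (fdr, p, set name).  Returns columns
    ``set_name, k, n, K, N, p, fdr, enrichment_ratio, significant``.
    """
    universe = set(universe)
    cols = ["set_name", "k", "n", "K", "N", "p", "fdr", "enrichment_ratio", "significant"]
    rows = []
    for name, gs in collection.items():
        if len(set(gs.genes) & universe) < min_set:
            continue
        row = ora_hypergeometric(query, gs, universe)
        rows.append(row.__dict__ | {"set_name": name})
    if not rows:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["fdr"] < fdr_threshold
    table = table.sort_values(["fdr", "p", "set_name"], kind="stable").reset_index(drop=True)
    return table[cols]
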