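"""Single-trait eQTL genome scan on RI genotypes.

The linkage statistic at a marker is the likelihood-ratio statistic (LRS)
of a two-class Gaussian mean model against the grand-mean null:

    LRS = n * ln(SS0 / SS1)

where SS0 is the total sum of squares about the grand mean and SS1 the
pooled within-genotype-class sum of squares.  LOD = LRS / (2 ln 10).
Because RI genotypes are homozygous and dense, the scan evaluates genotyped
markers only (no pseudomarker interpolation).  Genome-wide significance
(alpha = 0.05) and suggestive (alpha = 0.63, about one false positive per
scan) LRS thresholds come from permuting the trait across strains and
taking empirical quantiles of the per-permutation maximum LRS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, ValidationError

__all__ = [
    "LOD_DIVISOR",
    "QtlScan",
    "QtlPeak",
    "marker_lrs",
    "genome_scan",
    "permutation_thresholds",
    "support_interval",
    "classify_cis_trans",
    "lrs_to_lod",
]

#: LRS -> LOD conversion divisor, 2 * ln(10).
LOD_DIVISOR = 2.0 * np.log(10.0)

_DEFAULT_LRS_CEILING = 1e6


def lrs_to_lod(lrs: float | np.ndarray) -> float | np.ndarray:
    return lrs / LOD_DIVISOR


@dataclass
class QtlScan:
    """Per-marker LRS curve plus permutation thresholds (when computed).

    ``table`` columns: marker, chrom, pos_mb, lrs, additive (mean(D) -
    mean(B), log2 units), polymorphic.  Monomorphic markers are flagged and
    carry NaN statistics.
    """

    table: pd.DataFrame
    significant_lrs: float | None = None
    suggestive_lrs: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def top_marker(self, chrom: str | None = None) -> pd.Series:
        sub = self.table[self.table["polymorphic"]]
        if chrom is not None:
            sub = sub[sub["chrom"].astype(str) == str(chrom)]
        if sub.empty:
            raise ValidationError(f"no polymorphic markers{f' on chromosome {chrom}' if chrom else ''}")
        return sub.loc[sub["lrs"].idxmax()]

    @property
    def max_lrs(self) -> float:
        return float(self.table.loc[self.table["polymorphic"], "lrs"].max())


@dataclass
class QtlPeak:
    """A QTL peak with its 1.5-LOD support interval and cis/trans label."""

    chrom: str
    pos_mb: float
    lrs: float
    interval_start_mb: float
    interval_end_mb: float
    regulation: str | None = None

    @property
    def lod(self) -> float:
        return float(lrs_to_lod(self.lrs))


def marker_lrs(y, g, lrs_ceiling: float = _DEFAULT_LRS_CEILING) -> tuple[float, float]:
    """LRS and additive effect for one marker.

    Requires both genotype classes present and n >= 4.  A trait with zero
    total variance scores LRS = 0; a perfect within-class fit (SS1 = 0) is
    clamped to ``lrs_ceiling`` with a warning.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    if y.shape != g.shape:
        raise ValidationError("trait and genotype vectors must have equal length")
    n = y.size
    if n < 4:
        raise ValidationError(f"need at least 4 strains, got {n}")
    mask1 = g == 1
    mask0 = g == 0
    if not mask1.any() or not mask0.any():
        raise ValidationError("monomorphic marker: both genotype classes required")
    additive = float(y[mask1].mean() - y[mask0].mean())
    ss0 = float(((y - y.mean()) ** 2).sum())
    if ss0 == 0.0:
        return 0.0, additive
    ss1 = float(((y[mask0] - y[mask0].mean()) ** 2).sum()
                + ((y[mask1] - y[mask1].mean()) ** 2).sum())
    if ss1 == 0.0:
        warnings.warn("perfect genotype fit (SS1 = 0): LRS clamped to ceiling", stacklevel=2)
        return float(lrs_ceiling), additive
    return max(0.0, float(n * np.log(ss0 / ss1))), additive


def _scan_matrix(Y: np.ndarray, G: np.ndarray, lrs_ceiling: float = _DEFAULT_LRS_CEILING,
                 warn_perfect: bool = True) -> np.ndarray:
    """Vectorised LRS for traits Y (t x n) across markers G (n x m).

    Assumes every column of G is polymorphic.  Returns a (t x m) LRS matrix.
    """
    n = G.shape[0]
    n1 = G.sum(axis=0)
    n0 = n - n1
    tot = Y.sum(axis=1, keepdims=True)
    sq = (Y**2).sum(axis=1, keepdims=True)
    s1 = Y @ G
    s0 = tot - s1
    ss1 = sq - s1**2 / n1 - s0**2 / n0
    ss0 = sq - tot**2 / n
    ss1 = np.maximum(ss1, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrs = n * np.log(ss0 / ss1)
    perfect = (ss1 == 0.0) & (ss0 > 0.0)
    if perfect.any():
        if warn_perfect:
            warnings.warn("perfect genotype fit (SS1 = 0): LRS clamped to ceiling", stacklevel=2)
        lrs = np.where(perfect, lrs_ceiling, lrs)
    lrs = np.where(ss0 == 0.0, 0.0, lrs)
    return np.maximum(lrs, 0.0)


def genome_scan(y, genotypes: GenotypeMatrix,
                lrs_ceiling: float = _DEFAULT_LRS_CEILING) -> QtlScan:
    """LRS at every polymorphic marker, in map order.

    ``y`` may be a plain vector in strain order or a Series indexed by
    strain id (reindexed to the genotype panel).
    """
    y = _align_trait(y, genotypes)
    G = genotypes.codes.to_numpy(dtype=float)
    n1 = G.sum(axis=0)
    poly = (n1 > 0) & (n1 < G.shape[0])
    if not poly.any():
        raise ValidationError("no polymorphic markers in genotype matrix")
    lrs = np.full(G.shape[1], np.nan)
    additive = np.full(G.shape[1], np.nan)
    Gp = G[:, poly]
    lrs[poly] = _scan_matrix(y[None, :], Gp, lrs_ceiling)[0]
    s1 = y @ Gp
    n1p = Gp.sum(axis=0)
    additive[poly] = s1 / n1p - (y.sum() - s1) / (G.shape[0] - n1p)
    table = pd.DataFrame(
        {
            "marker": genotypes.marker_ids,
            "chrom": genotypes.markers["chrom"].astype(str).to_numpy(),
            "pos_mb": genotypes.markers["pos_mb"].to_numpy(dtype=float),
            "lrs": lrs,
            "additive": additive,
            "polymorphic": poly,
        }
    )
    return QtlScan(table)


def permutation_thresholds(
    y,
    genotypes: GenotypeMatrix,
    n_perm: int = 1000,
    alpha_sig: float = 0.05,
    alpha_sug: float = 0.63,
    seed: int | None = None,
    lrs_ceiling: float = _DEFAULT_LRS_CEILING,
) -> tuple[float, float]:
    """Genome-wide LRS thresholds from a permutation null.

    The trait is permuted across strains ``n_perm`` times; thresholds are
    the empirical (1 - alpha) type-7 quantiles of the per-permutation
    genome-wide maximum LRS.
    """
    if seed is None:
        raise ValidationError("permutation_thresholds requires an explicit seed")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} < 100: thresholds will be noisy", stacklevel=2)
    y = _align_trait(y, genotypes)
    rng = np.random.default_rng(seed)
    G = genotypes.codes.to_numpy(dtype=float)
    n1 = G.sum(axis=0)
    Gp = G[:, (n1 > 0) & (n1 < G.shape[0])]
    if Gp.shape[1] == 0:
        raise ValidationError("no polymorphic markers in genotype matrix")
    Y = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    maxima = _scan_matrix(Y, Gp, lrs_ceiling, warn_perfect=False).max(axis=1)
    sig, sug = np.quantile(maxima, [1.0 - alpha_sig, 1.0 - alpha_sug], method="linear")
    return float(sig), float(sug)


def support_interval(scan: QtlScan, chromosome: str, drop_lod: float = 1.5) -> QtlPeak:
    """Peak and LOD-drop support interval on one chromosome.

    The interval extends to the outermost contiguous marker whose LOD stays
    within ``drop_lod`` of the peak, then includes one additional flanking
    marker on each side (the first marker failing the drop), clipped at the
    chromosome ends.  Ties at the peak break toward the smaller position.
    """
    sub = scan.table[
        (scan.table["chrom"].astype(str) == str(chromosome)) & scan.table["polymorphic"]
    ].reset_index(drop=True)
    if sub.empty:
        raise ValidationError(f"chromosome {chromosome!r} not present in scan")
    lod = lrs_to_lod(sub["lrs"].to_numpy(dtype=float))
    peak_idx = int(np.argmax(lod))  # first max = smaller position (map order)
    cutoff = lod[peak_idx] - drop_lod
    left = peak_idx
    while left > 0 and lod[left - 1] >= cutoff:
        left -= 1
    right = peak_idx
    while right < len(lod) - 1 and lod[right + 1] >= cutoff:
        right += 1
    left = max(0, left - 1)
    right = min(len(lod) - 1, right + 1)
    return QtlPeak(
        chrom=str(chromosome),
        pos_mb=float(sub.loc[peak_idx, "pos_mb"]),
        lrs=float(sub.loc[peak_idx, "lrs"]),
        interval_start_mb=float(sub.loc[left, "pos_mb"]),
        interval_end_mb=float(sub.loc[right, "pos_mb"]),
    )


def classify_cis_trans(
    peak: QtlPeak,
    gene_chrom: str | None,
    gene_pos_mb: float | None,
    window_mb: float = 10.0,
) -> str:
    """cis iff the peak sits on the gene's chromosome within ``window_mb`` (inclusive)."""
    if gene_chrom is None or gene_pos_mb is None or (
        isinstance(gene_pos_mb, float) and np.isnan(gene_pos_mb)
    ):
        raise ValidationError("gene annotation (chromosome and position) required")
    same = str(peak.chrom) == str(gene_chrom)
    return "cis" if same and abs(peak.pos_mb - float(gene_pos_mb)) <= window_mb else "trans"


def _align_trait(y, genotypes: GenotypeMatrix) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [s for s in genotypes.strain_ids if s not in y.index]
        if missing:
            raise ValidationError(f"trait missing strains: {missing[:5]}")
        y = y.reindex(genotypes.strain_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if y.size != genotypes.n_strains:
            raise ValidationError(
                f"trait length {y.size} != number of strains {genotypes.n_strains}"
            )
    if not np.isfinite(y).all():
        raise ValidationError("trait vector must be finite (no missing values in scans)")
    return y
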