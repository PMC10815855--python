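"""Core in-memory containers shared by all analysis stages.

The containers are thin, validated wrappers around :class:`pandas.DataFrame`
objects: a genotype matrix for a recombinant-inbred (RI) panel, a log2
expression matrix with optional genomic annotation, a (possibly sparse)
strain-by-trait phenotype table, and a named collection of gene sets.
Validation happens at construction time so that downstream code can assume
the documented invariants.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ConfigError",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "TraitTable",
    "GeneSet",
    "GeneSetCollection",
    "EVIDENCE_COLUMNS",
    "FUNCTIONAL_SOURCES",
    "validate_evidence",
    "chrom_sort_key",
]


class FormatError(ValueError):
    """Malformed external input (wrong layout, unknown symbol, bad field count)."""


class ValidationError(ValueError):
    """A container invariant or an operation precondition is violated."""


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


#: Functional-evidence sources recognised by the candidate scoring scheme.
FUNCTIONAL_SOURCES = ("RGD_causal", "GWAS_catalog", "MGI", "IMPC", "KEGG", "Alliance")

#: Columns of an evidence table (one row per candidate gene).
EVIDENCE_COLUMNS = (
    "gene",
    "chrom",
    "pos_mb",
    "mean_expression",
    "has_coding_variant",
    "is_cis_regulated",
    "sig_corr_with_focal",
    "functional_sources",
)


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Sort key placing numeric chromosomes first (1, 2, ...), then X, Y, M/MT."""
    c = str(chrom).removeprefix("chr").removeprefix("Chr")
    if c.isdigit():
        return (0, int(c))
    special = {"X": 100, "Y": 101, "M": 102, "MT": 102}
    if c.upper() in special:
        return (0, special[c.upper()])
    return (1, c)


@dataclass
class GenotypeMatrix:
    """Biallelic homozygous genotypes for an RI panel.

    Parameters
    ----------
    codes
        strains x markers integer matrix; 0 = B-allele homozygote,
        1 = D-allele homozygote.  RI strains are fully inbred, so no
        heterozygote code exists.
    markers
        Per-marker metadata indexed by marker id with columns ``chrom``
        (chromosome label), ``pos_mb`` (physical position, megabases) and
        optionally ``pos_cm`` (genetic position, centimorgans).  Markers must
        be sorted by (chromosome, position) with strictly increasing
        positions within each chromosome.
    """

    codes: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        if self.codes.shape[0] == 0 or self.codes.shape[1] == 0:
            raise ValidationError("genotype matrix needs at least one strain and one marker")
        if not self.codes.columns.equals(self.markers.index):
            raise ValidationError("codes columns and marker metadata index differ")
        vals = self.codes.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = sorted(set(np.unique(vals)) - {0, 1})
            raise ValidationError(
                f"genotype codes must be 0 (B) or 1 (D); found {bad} — heterozygote not supported"
            )
        if self.codes.columns.has_duplicates or self.codes.index.has_duplicates:
            raise ValidationError("duplicate marker or strain identifiers")
        for col in ("chrom", "pos_mb"):
            if col not in self.markers.columns:
                raise ValidationError(f"marker metadata is missing column {col!r}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        chroms = self.markers["chrom"].astype(str).to_numpy()
        pos = self.markers["pos_mb"].to_numpy(dtype=float)
        seen: list[str] = []
        for i, c in enumerate(chroms):
            if not seen or seen[-1] != c:
                if c in seen:
                    raise ValidationError(f"chromosome {c} appears in non-contiguous blocks")
                seen.append(c)
            elif pos[i] <= pos[i - 1]:
                raise ValidationError(
                    f"marker positions not strictly increasing on chromosome {c} "
                    f"(marker {self.markers.index[i]!r} at {pos[i]} Mb after {pos[i - 1]} Mb)"
                )
        order = sorted(seen, key=chrom_sort_key)
        if seen != order:
            raise ValidationError(f"chromosomes out of order: {seen} (expected {order})")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_strains(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def chromosome_markers(self, chrom: str) -> pd.DataFrame:
        """Metadata rows for one chromosome (map order preserved)."""
        sub = self.markers[self.markers["chrom"].astype(str) == str(chrom)]
        if sub.empty:
            raise ValidationError(f"chromosome {chrom!r} not present in genotype map")
        return sub

    def equals(self, other: "GenotypeMatrix") -> bool:
        return self.codes.equals(other.codes) and self.markers.drop(
            columns=[c for c in self.markers.columns if self.markers[c].isna().all()]
        ).equals(
            other.markers.drop(
                columns=[c for c in other.markers.columns if other.markers[c].isna().all()]
            )
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-scale expression with optional gene annotation.

    ``gene_annotation`` (if given) is indexed by gene id with columns
    ``chrom`` and ``pos_mb``; every annotated gene must carry both.
    ``sample_group`` (if given) labels each sample, e.g. a strain id or a
    case/control group.
    """

    values: pd.DataFrame
    gene_annotation: pd.DataFrame | None = None
    sample_group: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must be finite")
        if self.gene_annotation is not None:
            ann = self.gene_annotation
            for col in ("chrom", "pos_mb"):
                if col not in ann.columns:
                    raise ValidationError(f"gene annotation is missing column {col!r}")
            if ann[["chrom", "pos_mb"]].isna().any().any():
                raise ValidationError("annotated genes must have both chromosome and position")
        if self.sample_group is not None:
            missing = self.values.columns.difference(self.sample_group.index)
            if len(missing) > 0:
                raise ValidationError(f"samples without group label: {list(missing)[:5]}")
            self.sample_group = self.sample_group.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def gene_location(self, gene: str) -> tuple[str, float]:
        """(chromosome, position Mb) for an annotated gene."""
        if self.gene_annotation is None or gene not in self.gene_annotation.index:
            raise ValidationError(f"gene {gene!r} has no genomic annotation")
        row = self.gene_annotation.loc[gene]
        return str(row["chrom"]), float(row["pos_mb"])

    def equals(self, other: "ExpressionMatrix") -> bool:
        if not np.allclose(self.values.to_numpy(), other.values.to_numpy()):
            return False
        return self.values.index.equals(other.values.index) and self.values.columns.equals(
            other.values.columns
        )


@dataclass
class TraitTable:
    """Strains x traits phenotype values; missing values (NaN) allowed."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("duplicate strain or trait identifiers")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} contains duplicate members")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self.genes


@dataclass
class GeneSetCollection(Mapping):
    """Ordered name -> :class:`GeneSet` mapping (GMT-file semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValidationError(f"duplicate gene set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    @classmethod
    def from_dict(cls, d: Mapping[str, list[str] | tuple[str, ...]]) -> "GeneSetCollection":
        coll = cls()
        for name, genes in d.items():
            coll.add(GeneSet(name, "", tuple(genes)))
        return coll


def validate_evidence(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an evidence table in place.

    ``functional_sources`` entries are normalised to frozensets drawn from
    :data:`FUNCTIONAL_SOURCES`; flag columns are coerced to bool.
    """
    missing = [c for c in EVIDENCE_COLUMNS if c not in table.columns and c not in ("chrom", "pos_mb")]
    if missing:
        raise ValidationError(f"evidence table missing columns: {missing}")

    def _norm(src: object) -> frozenset[str]:
        if isinstance(src, frozenset):
            items: tuple[str, ...] = tuple(src)
        elif isinstance(src, (set, list, tuple)):
            items = tuple(src)
        elif src is None or (isinstance(src, float) and np.isnan(src)) or src == "":
            items = ()
        elif isinstance(src, str):
            items = tuple(s for s in src.split(";") if s)
        else:
            raise ValidationError(f"cannot interpret functional sources {src!r}")
        unknown = set(items) - set(FUNCTIONAL_SOURCES)
        if unknown:
            raise ValidationError(f"unknown functional sources: {sorted(unknown)}")
        return frozenset(items)

    table = table.copy()
    table["functional_sources"] = table["functional_sources"].map(_norm)
    for col in ("has_coding_variant", "is_cis_regulated", "sig_corr_with_focal"):
        table[col] = table[col].astype(bool)
    table["mean_expression"] = table["mean_expression"].astype(float)
    return table


def _dataclass_fields(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
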