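"""Readers and writers for the external file formats.

Supported formats: plain TSV matrices (genotypes, expression, traits,
evidence, result tables), a GeneNetwork-like ``.geno`` genotype layout,
GMT gene-set files and JSON result tables.  All readers validate their
input and raise :class:`~sysgen.types.FormatError` with positional
diagnostics; every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EVIDENCE_COLUMNS,
    FormatError,
    GeneSet,
    GeneSetCollection,
    GenotypeMatrix,
    ExpressionMatrix,
    TraitTable,
    ValidationError,
    validate_evidence,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_traits",
    "write_traits",
    "read_gmt",
    "write_gmt",
    "read_evidence",
    "write_evidence",
    "write_results",
    "read_results",
]

#: Accepted allele symbols.  RI strains are homozygous, so H is rejected.
_ALLELE_CODES = {"B": 0, "D": 1, "0": 0, "1": 1}

_FLOAT_FMT = "%.6g"


def _decode_allele(symbol: str, row: int, column: str) -> int:
    s = symbol.strip()
    if s in ("H", "h"):
        raise FormatError(
            f"heterozygote not supported (allele 'H' at data row {row}, strain {column!r})"
        )
    if s not in _ALLELE_CODES:
        raise FormatError(
            f"unknown allele symbol {symbol!r} at data row {row}, strain {column!r}"
        )
    return _ALLELE_CODES[s]


def read_genotypes(path: str | Path, dialect: str = "auto") -> GenotypeMatrix:
    """Read an RI genotype table.

    ``dialect="tsv"`` expects a header ``marker  chrom  pos_mb  [pos_cm]``
    followed by one column per strain; ``dialect="geno"`` expects the
    GeneNetwork-like layout ``Chr  Locus  cM  Mb  <strain...>`` with optional
    ``#``/``@`` comment lines.  Allele symbols may be B/D or 0/1.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "geno" if path.suffix == ".geno" else "tsv"
    if dialect == "geno":
        return _read_geno(path)
    if dialect == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty genotype file")
    header = lines[0].rstrip("\n").split("\t")
    fixed = ["marker", "chrom", "pos_mb"]
    if header[: len(fixed)] != fixed:
        raise FormatError(f"{path}: header must start with {fixed}, got {header[:3]}")
    has_cm = len(header) > 3 and header[3] == "pos_cm"
    n_meta = 4 if has_cm else 3
    strains = header[n_meta:]
    if not strains:
        raise FormatError(f"{path}: no strain columns in header")
    return _parse_genotype_rows(
        path, lines[1:], strains, marker_col=0, chrom_col=1, mb_col=2,
        cm_col=3 if has_cm else None, n_meta=n_meta,
    )


def _read_geno(path: Path) -> GenotypeMatrix:
    raw = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith(("#", "@"))
    ]
    if not raw:
        raise FormatError(f"{path}: empty .geno file")
    header = raw[0].split("\t")
    expected = ["Chr", "Locus", "cM", "Mb"]
    if header[:4] != expected:
        raise FormatError(f"{path}: .geno header must start with {expected}, got {header[:4]}")
    strains = header[4:]
    if not strains:
        raise FormatError(f"{path}: no strain columns in header")
    return _parse_genotype_rows(
        path, raw[1:], strains, marker_col=1, chrom_col=0, mb_col=3, cm_col=2, n_meta=4
    )


def _parse_genotype_rows(path, rows, strains, *, marker_col, chrom_col, mb_col, cm_col, n_meta):
    markers, chroms, mbs, cms, codes = [], [], [], [], []
    for i, line in enumerate(rows, start=1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != n_meta + len(strains):
            raise FormatError(
                f"{path}: data row {i} has {len(fields)} fields, expected {n_meta + len(strains)}"
            )
        markers.append(fields[marker_col])
        chroms.append(fields[chrom_col])
        try:
            mbs.append(float(fields[mb_col]))
        except ValueError as exc:
            raise FormatError(f"{path}: bad position {fields[mb_col]!r} at data row {i}") from exc
        cms.append(float(fields[cm_col]) if cm_col is not None else np.nan)
        codes.append(
            [_decode_allele(sym, i, strains[j]) for j, sym in enumerate(fields[n_meta:])]
        )
    meta = pd.DataFrame(
        {"chrom": chroms, "pos_mb": mbs, "pos_cm": cms}, index=pd.Index(markers, name="marker")
    )
    code_df = pd.DataFrame(
        np.asarray(codes, dtype=np.int8).T, index=pd.Index(strains, name="strain"),
        columns=meta.index,
    )
    try:
        return GenotypeMatrix(code_df, meta)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_genotypes(gm: GenotypeMatrix, path: str | Path, dialect: str = "auto") -> None:
    path = Path(path)
    if dialect == "auto":
        dialect = "geno" if path.suffix == ".geno" else "tsv"
    letters = np.where(gm.codes.to_numpy() == 0, "B", "D")
    has_cm = "pos_cm" in gm.markers.columns and not gm.markers["pos_cm"].isna().all()
    with path.open("w") as fh:
        if dialect == "geno":
            fh.write("\t".join(["Chr", "Locus", "cM", "Mb", *gm.strain_ids]) + "\n")
            for j, (mid, row) in enumerate(gm.markers.iterrows()):
                cm = row["pos_cm"] if has_cm else 0.0
                fh.write(
                    "\t".join(
                        [str(row["chrom"]), str(mid), _FLOAT_FMT % cm,
                         _FLOAT_FMT % row["pos_mb"], *letters[:, j]]
                    ) + "\n"
                )
        elif dialect == "tsv":
            cols = ["marker", "chrom", "pos_mb"] + (["pos_cm"] if has_cm else [])
            fh.write("\t".join(cols + gm.strain_ids) + "\n")
            for j, (mid, row) in enumerate(gm.markers.iterrows()):
                meta = [str(mid), str(row["chrom"]), _FLOAT_FMT % row["pos_mb"]]
                if has_cm:
                    meta.append(_FLOAT_FMT % row["pos_cm"])
                fh.write("\t".join(meta + list(letters[:, j])) + "\n")
        else:
            raise ValueError(f"unknown genotype dialect {dialect!r}")


def read_expression(
    path: str | Path,
    annotation_path: str | Path | None = None,
    labels_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column ``gene``).

    ``annotation_path`` may point to a TSV with columns ``gene``, ``chrom``,
    ``pos_mb``; ``labels_path`` to a TSV with columns ``sample``, ``group``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    ann = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
        ann.index = ann.index.astype(str)
    groups = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", index_col=0)
        if "group" not in lab.columns:
            raise FormatError(f"{labels_path}: labels file needs a 'group' column")
        groups = lab["group"].astype(str)
        groups.index = groups.index.astype(str)
    return ExpressionMatrix(df.astype(float), ann, groups)


def write_expression(em: ExpressionMatrix, path: str | Path,
                     annotation_path: str | Path | None = None,
                     labels_path: str | Path | None = None) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)
    if annotation_path is not None and em.gene_annotation is not None:
        em.gene_annotation.to_csv(
            annotation_path, sep="\t", index_label="gene", float_format=_FLOAT_FMT
        )
    if labels_path is not None and em.sample_group is not None:
        em.sample_group.rename("group").to_csv(labels_path, sep="\t", index_label="sample")


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return TraitTable(df.astype(float))


def write_traits(tt: TraitTable, path: str | Path) -> None:
    tt.values.to_csv(path, sep="\t", index_label="strain", float_format=_FLOAT_FMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are removed with a warning; a line with
    fewer than three fields is a format error naming the line number.
    """
    coll = GeneSetCollection()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno} has {len(fields)} fields; "
                "GMT needs name, description and at least one member"
            )
        name, desc, *members = fields
        members = [m for m in members if m]
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            warnings.warn(
                f"{path}: line {lineno} ({name!r}): duplicate members removed",
                stacklevel=2,
            )
        coll.add(GeneSet(name, desc, tuple(unique)))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in coll.values():
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_evidence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"gene": str, "chrom": str, "functional_sources": str},
        keep_default_na=True,
    )
    if "functional_sources" in df.columns:
        df["functional_sources"] = df["functional_sources"].fillna("")
    for col in ("has_coding_variant", "is_cis_regulated", "sig_corr_with_focal"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
    return validate_evidence(df)


def write_evidence(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["functional_sources"] = out["functional_sources"].map(
        lambda s: ";".join(sorted(s)) if not isinstance(s, str) else s
    )
    cols = [c for c in EVIDENCE_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _round_sig(x: float, sig: int = 6) -> float:
    return float(_FLOAT_FMT % x)


def write_results(table: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Serialise a result table losslessly (6 significant digits for floats).

    Row order is preserved exactly as given (deterministic output).
    """
    path = Path(path)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif format == "json":
        records = []
        for _, row in table.iterrows():
            rec = {}
            for col, val in row.items():
                if isinstance(val, (float, np.floating)):
                    rec[col] = _round_sig(float(val))
                elif isinstance(val, (np.integer,)):
                    rec[col] = int(val)
                elif isinstance(val, (np.bool_,)):
                    rec[col] = bool(val)
                elif isinstance(val, frozenset):
                    rec[col] = sorted(val)
                else:
                    rec[col] = val
            records.append(rec)
        path.write_text(
            json.dumps({"columns": list(table.columns), "rows": records}, indent=1) + "\n"
        )
    else:
        raise ValueError(f"unknown result format {format!r}")


def read_results(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["rows"], columns=payload["columns"])
    raise ValueError(f"unknown result format {format!r}")
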