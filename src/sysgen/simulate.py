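"""Synthetic study-condition generator.

Emulates everything the downstream stages consume without any external
downloads: a recombinant-inbred (RI) genotype panel with realistic linkage,
log2 expression with planted cis/trans eQTLs and correlated background
blocks, trait panels linearly loaded on genes, and a case/control cohort
whose samples are mixtures of cell-type signature profiles.

Genotypes follow standard RI theory for sib-mated panels: the meiotic
recombination fraction r between adjacent markers comes from the Haldane
map function r = (1 - exp(-2d/100))/2 for a distance of d centimorgans, and
the fixed RI strain inherits a recombinant haplotype with the map-expanded
probability R = 4r / (1 + 6r).  Chromosomes and strains are independent;
the first marker of every chromosome is B or D with probability 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .types import (
    ConfigError,
    ExpressionMatrix,
    GeneSetCollection,
    GenotypeMatrix,
    TraitTable,
)

__all__ = [
    "ChromosomeMap",
    "PlantedEqtl",
    "ExtraGene",
    "CorrelatedBlock",
    "RegulatorEdge",
    "TraitSpec",
    "CohortConfig",
    "SimConfig",
    "default_marker_map",
    "recombinant_fraction",
    "ri_transition_probability",
    "simulate_ri_genotypes",
    "simulate_expression",
    "simulate_traits",
    "simulate_cohort",
]


@dataclass
class ChromosomeMap:
    """Evenly spaced marker grid on one chromosome."""

    name: str
    n_markers: int
    spacing_cm: float = 5.0
    spacing_mb: float = 7.5
    start_mb: float = 3.0
    start_cm: float = 0.0


@dataclass
class PlantedEqtl:
    """A gene whose expression loads additively on one marker.

    ``beta`` is the additive effect in log2 units (D-allele mean minus
    B-allele mean); ``kind`` records the cis/trans intent and controls where
    the gene is annotated (within 10 Mb of the marker for cis, on another
    chromosome for trans).  ``baseline`` overrides the global baseline mean.
    """

    gene: str
    marker: str
    beta: float
    kind: str = "trans"
    baseline: float | None = None


@dataclass
class ExtraGene:
    """A noise-only gene with explicit annotation (e.g. a focal gene whose
    variation enters through regulator edges rather than a planted marker)."""

    gene: str
    chrom: str
    pos_mb: float
    baseline: float | None = None


@dataclass
class CorrelatedBlock:
    """Partner genes correlated with an anchor gene.

    Each partner equals ``rho * z(anchor) + sqrt(1 - rho^2) * noise`` on the
    standardised scale, so the partner-anchor Pearson correlation is exactly
    ``rho`` in expectation and partner-partner correlation is ``rho**2``.
    """

    anchor_gene: str
    n_partners: int
    rho: float
    prefix: str = "partner"


@dataclass
class RegulatorEdge:
    """Causal gene -> gene edge: target += weight * (source - mean(source))."""

    source: str
    target: str
    weight: float = 1.0


@dataclass
class TraitSpec:
    """Trait built as a linear combination of gene expression plus noise."""

    name: str
    loadings: dict[str, float]
    noise_sd: float = 0.0


@dataclass
class CohortConfig:
    """Case/control cohort built from cell-type signature mixtures.

    Each sample's expression is ``baseline + amplitude * sum_c p_c * 1[gene in
    signature_c] + noise``; mixing proportions ``p`` are drawn from a
    Dirichlet centred on the group mean vector (``concentration=None`` uses
    the group means exactly).  ``tracked_genes`` maps a gene name to
    ``(cell_type, coupling)``: its expression follows that cell type's mixing
    proportion, which makes gene-infiltration correlations recoverable.
    """

    n_case: int
    n_control: int
    signatures: dict[str, list[str]]
    case_props: dict[str, float]
    control_props: dict[str, float]
    concentration: float | None = 50.0
    noise_sd: float = 0.25
    amplitude: float = 4.0
    baseline: float = 5.0
    n_background_genes: int = 40
    tracked_genes: dict[str, tuple[str, float]] = field(default_factory=dict)


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with one global seed.

    The seed is split into independent per-generator streams, so each stage
    is reproducible on its own and regenerating with the same config gives
    bit-identical matrices.
    """

    seed: int
    n_strains: int = 40
    chromosomes: list[ChromosomeMap] = field(default_factory=lambda: default_marker_map())
    planted_eqtls: list[PlantedEqtl] = field(default_factory=list)
    extra_genes: list[ExtraGene] = field(default_factory=list)
    correlated_blocks: list[CorrelatedBlock] = field(default_factory=list)
    regulator_edges: list[RegulatorEdge] = field(default_factory=list)
    residual_sd: float = 0.5
    n_background_genes: int = 60
    block_size: int = 10
    block_rho: float = 0.6
    baseline_mean: float = 8.0
    traits: list[TraitSpec] = field(default_factory=list)
    cohort: CohortConfig | None = None

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ConfigError("n_strains must be >= 1")
        if not self.chromosomes or any(c.n_markers < 1 for c in self.chromosomes):
            raise ConfigError("marker map must contain at least one marker per chromosome")
        if not self.residual_sd > 0:
            raise ConfigError("residual_sd must be > 0")
        if not 0 <= self.block_rho < 1:
            raise ConfigError("block correlation rho must satisfy 0 <= rho < 1")
        for pe in self.planted_eqtls:
            if not np.isfinite(pe.beta):
                raise ConfigError(f"planted effect for {pe.gene!r} is not finite")
            if pe.kind not in ("cis", "trans"):
                raise ConfigError(f"eQTL kind must be 'cis' or 'trans', got {pe.kind!r}")
        if self.cohort is not None:
            _validate_cohort(self.cohort)

    # -- seed plumbing ---------------------------------------------------
    def rng(self, stage: str) -> np.random.Generator:
        """Independent generator stream for a named stage."""
        order = ("genotypes", "expression", "traits", "cohort")
        if stage not in order:
            raise ConfigError(f"unknown rng stage {stage!r}")
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(children[order.index(stage)])

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(open(path))
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        raw["chromosomes"] = [ChromosomeMap(**c) for c in raw.get("chromosomes", [])] or None
        if raw["chromosomes"] is None:
            raw.pop("chromosomes")
        raw["planted_eqtls"] = [PlantedEqtl(**p) for p in raw.get("planted_eqtls", [])]
        raw["extra_genes"] = [ExtraGene(**g) for g in raw.get("extra_genes", [])]
        raw["correlated_blocks"] = [CorrelatedBlock(**b) for b in raw.get("correlated_blocks", [])]
        raw["regulator_edges"] = [RegulatorEdge(**e) for e in raw.get("regulator_edges", [])]
        raw["traits"] = [TraitSpec(**t) for t in raw.get("traits", [])]
        if raw.get("cohort") is not None:
            c = dict(raw["cohort"])
            c["tracked_genes"] = {
                g: tuple(v) for g, v in (c.get("tracked_genes") or {}).items()
            }
            raw["cohort"] = CohortConfig(**c)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_cohort(c: CohortConfig) -> None:
    if c.n_case < 1 or c.n_control < 1:
        raise ConfigError("cohort needs at least one case and one control sample")
    if not c.signatures:
        raise ConfigError("cohort needs at least one cell-type signature set")
    cells = set(c.signatures)
    for label, props in (("case", c.case_props), ("control", c.control_props)):
        if set(props) != cells:
            raise ConfigError(f"{label} proportions must cover exactly the signature cell types")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"{label} mixing proportions sum to {total}, expected 1")
        if any(p < 0 for p in props.values()):
            raise ConfigError(f"{label} mixing proportions must be non-negative")
    for gene, (cell, _w) in c.tracked_genes.items():
        if cell not in cells:
            raise ConfigError(f"tracked gene {gene!r} references unknown cell type {cell!r}")


def default_marker_map() -> list[ChromosomeMap]:
    """Five mouse-like chromosomes, 20 markers each at 5 cM / 7.5 Mb spacing."""
    return [ChromosomeMap(name=str(i + 1), n_markers=20) for i in range(5)]


# ---------------------------------------------------------------------------
# genotypes


def recombinant_fraction(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: r = (1 - exp(-2d/100)) / 2 for d in centimorgans."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


def ri_transition_probability(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Probability that adjacent markers differ in a sib-mated RI strain.

    RI map expansion R = 4r / (1 + 6r) with r from :func:`recombinant_fraction`.
    """
    r = recombinant_fraction(d_cm)
    return 4.0 * r / (1.0 + 6.0 * r)


def simulate_ri_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate homozygous RI genotypes as a Markov chain along each chromosome."""
    rng = config.rng("genotypes")
    n = config.n_strains
    blocks, meta_rows, marker_ids = [], [], []
    for chrom in config.chromosomes:
        m = chrom.n_markers
        codes = np.empty((n, m), dtype=np.int8)
        codes[:, 0] = rng.integers(0, 2, size=n)
        if m > 1:
            flip_p = ri_transition_probability(chrom.spacing_cm)
            flips = rng.random(size=(n, m - 1)) < flip_p
            # cumulative XOR of flips along the chromosome
            codes[:, 1:] = (codes[:, [0]] + np.cumsum(flips, axis=1)) % 2
        blocks.append(codes)
        for j in range(m):
            marker_ids.append(f"m{chrom.name}_{j + 1:03d}")
            meta_rows.append(
                {
                    "chrom": chrom.name,
                    "pos_mb": chrom.start_mb + j * chrom.spacing_mb,
                    "pos_cm": chrom.start_cm + j * chrom.spacing_cm,
                }
            )
    meta = pd.DataFrame(meta_rows, index=pd.Index(marker_ids, name="marker"))
    codes = pd.DataFrame(
        np.concatenate(blocks, axis=1),
        index=pd.Index([f"RI{i + 1:03d}" for i in range(n)], name="strain"),
        columns=meta.index,
    )
    return GenotypeMatrix(codes, meta)


# ---------------------------------------------------------------------------
# expression


def _annotation_for_planted(pe: PlantedEqtl, markers: pd.DataFrame,
                            chrom_names: list[str]) -> tuple[str, float]:
    row = markers.loc[pe.marker]
    if pe.kind == "cis":
        return str(row["chrom"]), float(row["pos_mb"]) + 1.0
    # trans: place the gene on the next chromosome over, mid-map
    others = [c for c in chrom_names if c != str(row["chrom"])]
    target = others[0] if others else str(row["chrom"])
    sub = markers[markers["chrom"].astype(str) == target]
    return target, float(sub["pos_mb"].median())


def simulate_expression(genotypes: GenotypeMatrix, config: SimConfig) -> ExpressionMatrix:
    """Expression with planted eQTLs, correlated blocks and regulator edges.

    Planted gene value for strain s is ``baseline + beta * code(s, marker) +
    residual_sd * eps``.  Background genes come in blocks with exchangeable
    correlation ``block_rho`` (single shared factor per block).  The matrix is
    on the 2Z+8-like log2 scale (global mean near 8).
    """
    rng = config.rng("expression")
    n = genotypes.n_strains
    markers = genotypes.markers
    chrom_names = list(dict.fromkeys(markers["chrom"].astype(str)))
    base = config.baseline_mean
    sd = config.residual_sd

    values: dict[str, np.ndarray] = {}
    ann_rows: dict[str, dict] = {}

    for pe in config.planted_eqtls:
        if pe.marker not in genotypes.codes.columns:
            raise ConfigError(f"planted marker {pe.marker!r} absent from genotypes")
        g = genotypes.codes[pe.marker].to_numpy(dtype=float)
        b0 = base if pe.baseline is None else pe.baseline
        values[pe.gene] = b0 + pe.beta * g + sd * rng.standard_normal(n)
        chrom, pos = _annotation_for_planted(pe, markers, chrom_names)
        ann_rows[pe.gene] = {"chrom": chrom, "pos_mb": pos}

    for eg in config.extra_genes:
        b0 = base if eg.baseline is None else eg.baseline
        values[eg.gene] = b0 + sd * rng.standard_normal(n)
        ann_rows[eg.gene] = {"chrom": str(eg.chrom), "pos_mb": float(eg.pos_mb)}

    # background genes: blocks with exchangeable correlation rho
    rho = config.block_rho
    n_bg = config.n_background_genes
    bsize = max(1, config.block_size)
    positions = _spread_positions(n_bg, markers, chrom_names)
    for start in range(0, n_bg, bsize):
        factor = rng.standard_normal(n)
        for k in range(start, min(start + bsize, n_bg)):
            eps = rng.standard_normal(n)
            z = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps
            gene = f"bg{k + 1:04d}"
            values[gene] = base + sd * z
            ann_rows[gene] = positions[k]

    # partner blocks correlated with an anchor gene (e.g. the focal gene)
    for blk in config.correlated_blocks:
        if blk.anchor_gene not in values:
            raise ConfigError(f"anchor gene {blk.anchor_gene!r} not generated")
        if not 0 <= blk.rho < 1:
            raise ConfigError("partner-block rho must satisfy 0 <= rho < 1")
        anchor = values[blk.anchor_gene]
        z_anchor = (anchor - anchor.mean()) / anchor.std(ddof=0)
        for k in range(blk.n_partners):
            eps = rng.standard_normal(n)
            z = blk.rho * z_anchor + np.sqrt(1.0 - blk.rho**2) * eps
            gene = f"{blk.prefix}{k + 1:04d}"
            values[gene] = base + sd * z
            ann_rows[gene] = _spread_positions(1, markers, chrom_names, offset=k)[0]

    # causal regulator edges, applied in declared order
    for edge in config.regulator_edges:
        for name in (edge.source, edge.target):
            if name not in values:
                raise ConfigError(f"regulator edge references unknown gene {name!r}")
        src = values[edge.source]
        values[edge.target] = values[edge.target] + edge.weight * (src - src.mean())

    vals = pd.DataFrame(values, index=genotypes.codes.index).T
    vals.index.name = "gene"
    ann = pd.DataFrame.from_dict(ann_rows, orient="index").reindex(vals.index)
    ann.index.name = "gene"
    return ExpressionMatrix(vals, ann)


def _spread_positions(count: int, markers: pd.DataFrame, chrom_names: list[str],
                      offset: int = 0) -> list[dict]:
    """Deterministic round-robin gene placement across the marker map."""
    out = []
    for k in range(count):
        chrom = chrom_names[(k + offset) % len(chrom_names)]
        sub = markers[markers["chrom"].astype(str) == chrom]
        lo, hi = float(sub["pos_mb"].min()), float(sub["pos_mb"].max())
        frac = (((k + offset) // len(chrom_names)) % 17 + 1) / 18.0
        out.append({"chrom": chrom, "pos_mb": lo + frac * (hi - lo)})
    return out


# ---------------------------------------------------------------------------
# traits


def simulate_traits(expression: ExpressionMatrix, config: SimConfig) -> TraitTable:
    """Traits as linear loadings on gene expression plus Gaussian noise."""
    rng = config.rng("traits")
    n = len(expression.sample_ids)
    cols = {}
    for spec in config.traits:
        y = np.zeros(n)
        for gene, w in spec.loadings.items():
            if gene not in expression.values.index:
                raise ConfigError(f"trait {spec.name!r} loads on unknown gene {gene!r}")
            y = y + w * expression.values.loc[gene].to_numpy(dtype=float)
        if spec.noise_sd > 0:
            y = y + spec.noise_sd * rng.standard_normal(n)
        cols[spec.name] = y
    values = pd.DataFrame(cols, index=pd.Index(expression.sample_ids, name="strain"))
    return TraitTable(values)


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Case/control cohort from planted cell-type mixtures.

    Returns the cohort expression matrix (with case/control sample groups)
    and the true per-sample mixing proportions.
    """
    if config.cohort is None:
        raise ConfigError("config has no cohort section")
    c = config.cohort
    rng = config.rng("cohort")
    cells = list(c.signatures)
    sig_genes = list(dict.fromkeys(g for genes in c.signatures.values() for g in genes))
    bg_genes = [f"cbg{k + 1:04d}" for k in range(c.n_background_genes)]
    genes = sig_genes + [g for g in c.tracked_genes if g not in sig_genes] + bg_genes

    samples, groups, prop_rows = [], [], []
    for group, n_grp, mean_props in (
        ("case", c.n_case, c.case_props),
        ("control", c.n_control, c.control_props),
    ):
        mean_vec = np.array([mean_props[cell] for cell in cells], dtype=float)
        for i in range(n_grp):
            if c.concentration is None:
                p = mean_vec.copy()
            else:
                alpha = np.maximum(c.concentration * mean_vec, 1e-6)
                p = rng.dirichlet(alpha)
            samples.append(f"{group}{i + 1:03d}")
            groups.append(group)
            prop_rows.append(p)
    props = pd.DataFrame(prop_rows, index=pd.Index(samples, name="sample"), columns=cells)

    membership = np.zeros((len(genes), len(cells)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for j, cell in enumerate(cells):
        for g in c.signatures[cell]:
            membership[gene_idx[g], j] = 1.0
    signal = c.baseline + c.amplitude * membership @ props.to_numpy().T
    for g, (cell, coupling) in c.tracked_genes.items():
        signal[gene_idx[g], :] += coupling * c.amplitude * props[cell].to_numpy()
    noise = c.noise_sd * rng.standard_normal(signal.shape) if c.noise_sd > 0 else 0.0
    values = pd.DataFrame(signal + noise, index=pd.Index(genes, name="gene"), columns=samples)
    em = ExpressionMatrix(values, None, pd.Series(groups, index=values.columns, name="group"))
    return em, props


def cohort_signature_collection(config: SimConfig) -> GeneSetCollection:
    """The cohort's cell-type signature sets as a GMT-style collection."""
    if config.cohort is None:
        raise ConfigError("config has no cohort section")
    return GeneSetCollection.from_dict(config.cohort.signatures)
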