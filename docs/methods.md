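# Methods

This note records the statistical models, conventions and design choices
behind `sysgen`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Normalization (2Z+8)

Expression values are log2-scale intensities rescaled to mean 8 and
standard deviation 2 ("2Z+8"), a convention that removes negative values
while leaving correlations and linkage statistics untouched (both are
invariant under per-vector affine maps). `normalize_2z8` supports two
axes:

- `axis="genes"` (default): every gene row is rescaled to mean 8, sd 2
  (sample sd, n−1). This is the operation's contractual form — the worked
  identity `[1, 2, 3] → [6, 8, 10]` holds, constant rows map to all-8, and
  the transform is idempotent.
- `axis="samples"`: every array (sample column) is rescaled instead. This
  is the convention under which per-gene mean expression remains a
  meaningful quantity — a gene can average 10.8 or 14.6 on this scale —
  so the pipeline uses it ahead of the mean-expression gates (> 7 for the
  correlation screen, ≥ 8 for candidate scoring). With per-gene
  normalization those gates would be vacuous, since every gene would
  average exactly 8.

Constant vectors have no z-score; mapping them to the target mean rather
than erroring keeps matrices aligned across stages.

## Correlation screens

Pearson r uses the product-moment formula on pairwise-complete
observations (missing phenotype values drop only the affected pairs —
phenotype panels for RI strains are sparse, and imputation is deliberately
avoided). The two-sided p-value comes from `t = r·√((n−2)/(1−r²))` on
n−2 df; |r| = 1 is reported with the smallest positive double rather than
p = 0. The screen's gates are a strict mean-expression cut (> 7) and a
nominal p < 0.05; no multiple-testing correction is applied at this stage
(that mirrors the transcriptome-screen convention; BH is available in the
differential-expression and enrichment stages where it belongs). The
human-style screen additionally requires |r| ≥ 0.5 (inclusive).

The fold difference across a panel is `2^(max − min)` of per-strain log2
means, reported on the unnormalized log2 scale.

## eQTL mapping

RI strains are fully inbred, so each marker splits the panel into two
homozygote classes and the single-marker model is a two-class Gaussian
mean model. The likelihood-ratio statistic against the grand-mean null is
`LRS = n·ln(SS₀/SS₁)` with MLE variances; `LOD = LRS/(2·ln 10) =
LRS/4.60517`. Conventions and edge cases:

- Scans evaluate genotyped markers only. RI panels are dense and
  homozygous, so marker-only evaluation is the honest reduction of
  interval mapping; no pseudomarker interpolation is performed.
- Monomorphic markers are flagged (`polymorphic = False`, NaN statistics)
  and skipped, not fatal.
- A constant trait scores LRS = 0; a perfect within-class fit (SS₁ = 0)
  is clamped to a configurable ceiling (10⁶) with a warning.
- The additive effect is mean(D) − mean(B) in log2 units.

**Permutation thresholds.** The trait is permuted across strains
(n_perm = 1000 by default, seed mandatory) and the genome-wide maximum LRS
recorded per permutation; the significant and suggestive thresholds are
the empirical 1−α quantiles (type-7, linear interpolation) at α = 0.05
and α = 0.63. The suggestive level follows the one-false-positive-per-scan
convention used by GeneNetwork-style mapping.

**Support intervals.** The 1.5-LOD interval extends from the peak to the
outermost contiguous marker whose LOD stays within 1.5 of the peak, then
includes one additional flanking marker on each side (the first marker
failing the drop), clipped at chromosome ends. Conventions differ between
tools; including the first failing flank is the conservative choice and is
asserted explicitly in the tests. Peak ties break toward the smaller
position.

**Cis/trans.** A peak is cis for a gene iff it lies on the gene's
chromosome within an inclusive 10 Mb window of the gene's position.

## Candidate scoring

Evidence per interval gene: mean expression (gate ≥ 8, inclusive);
presence of a damaging coding variant (non-synonymous, frameshift, or
stop gain/loss — synonymous variants never count); cis-regulation from the
gene's own scan; significant correlation with the focal gene (p < 0.05);
and functional sources. Weights: expression 1, variant 1, cis 1,
correlation 2, functional sources RGD-causal 2, GWAS Catalog 2, MGI /
IMPC / KEGG / Alliance 1 each, with the functional sub-score capped at 5 —
the cap is what makes the scheme's ceiling exactly
1+1+1+2+5 = 10. A source combination exceeding the cap (e.g. both
weight-2 sources plus two weight-1 sources) is truncated to 5. Genes with
total ≥ 5 (half the ceiling) are selected and ranked by total descending,
then genomic order (chromosome, position), stably.

The package ships the twelve published indicator rows for the *Rpl3l*
trans-QTL support intervals as package data; the generic "functional
evidence present" indicator is encoded as the weight-1 KEGG source and the
causal indicator as RGD-causal, which reproduces every published total.

## Enrichment

Over-representation only (upper-tail hypergeometric): for a query of n
universe genes and a set with K universe members, p = P(X ≥ k). The
universe defaults to all genes measured on the platform (rows of the
expression matrix) and is overridable — enrichment tools differ silently
on this choice, so it is explicit here. Query duplicates are removed and
query genes outside the universe dropped with a warning; sets with fewer
than 3 universe members are not tested. BH correction is applied across
all tested sets.

## ssGSEA infiltration

Scores follow the single-sample enrichment formulation: within a sample,
genes are ranked descending (average rank weights for ties; ties ordered
by gene id for determinism; the top gene carries rank weight N), and

```
ES = Σᵢ (P_in(i) − P_out(i)),
P_in(i)  = Σ_{j≤i, j∈S} w_j^α / Σ_{j∈S} w_j^α,
P_out(i) = #{j≤i, j∉S} / (N−K),
```

with α = 0.25 by default. Scores depend on expression only through
within-sample ranks and are therefore invariant under strictly increasing
transforms of a sample's values — this is asserted as a property test.
The implementation accepts any GMT of cell-type signatures; proprietary
reference marker sets and their compensation step are out of scope, so
raw ES values are exposed (plus an optional per-cell-type min-max
rescaling). Differential infiltration uses the two-sided Wilcoxon rank-sum
test — exact when the combined n ≤ 20 without ties, normal approximation
with tie correction otherwise; a Welch t-test is available behind a flag.

## Differential expression and sample exclusion

Samples are clustered on Euclidean distance between expression columns
(agglomerative, average linkage — the distance metric is the stated
convention, the linkage is this package's default and configurable), the
tree is cut into two clusters, and samples whose own group label differs
from their cluster's majority label are excluded; a tied majority aborts
with a request for manual review. The per-gene test is Welch's t
(two-sided) with BH correction at FDR < 0.05 — the simplest defensible
choice; moderated-variance estimators are deliberately out of scope.

## Synthetic-data generator

The generator defines the study conditions for all tests:

- **Genotypes.** Homozygous biallelic codes (0 = B, 1 = D) simulated as a
  Markov chain per chromosome: first marker Bernoulli(½), subsequent
  markers flip with R = 4r/(1+6r) (sib-mated RI map expansion) where r
  comes from the Haldane map function of the inter-marker distance.
  Chromosomes and strains independent. Default map: 5 chromosomes × 20
  markers at 5 cM / 7.5 Mb spacing — mouse-like chromosome extents with
  classic interval-mapping marker density; tests that need a specific
  marker count (500 or 1000) build denser maps explicitly.
- **Expression.** Planted gene = baseline + β·code + ε with ε ~ N(0,
  residual_sd); background genes in blocks with exchangeable correlation ρ
  via a shared factor (√ρ·f + √(1−ρ)·ε); optional partner blocks with
  exact correlation ρ to an anchor gene; optional causal regulator→target
  edges applied as centred additive contributions. Matrices sit on the
  2Z+8-like scale (global mean ≈ 8, default residual sd 0.5 log2 units).
  Cis-planted genes are annotated 1 Mb from their marker; trans-planted
  genes on another chromosome.
- **Traits.** Linear loadings on gene expression plus Gaussian noise.
- **Cohort.** Sample expression = baseline + amplitude·Σ_c p_c·1[gene ∈
  signature_c] + noise, with per-sample mixing proportions drawn from a
  Dirichlet centred on group-specific means (concentration 50 by default;
  `None` uses the means exactly). Tracked genes follow one cell type's
  proportion with a signed coupling, making gene–infiltration
  correlations recoverable by construction.

One global seed is split into independent per-stage streams
(`SeedSequence.spawn`), so each stage is reproducible in isolation and
regeneration is bit-identical.

What the generator does **not** emulate: probe-level microarray structure,
batch effects, sex or other covariates, realistic allele-frequency or
linkage-disequilibrium irregularities, heavy-tailed expression noise, and
realistic (small) effect sizes — planted effects are chosen for test
power, so passing tests demonstrate correctness of the machinery and
calibration of the statistics, not expected performance on real data.

## End-to-end scenario

The canonical pipeline scenario plants a regulator (`Reg1`) with a strong
cis-eQTL mid-chromosome 3 (β = 1.5, baseline 10) and a causal edge into
the focal gene (annotated on chromosome 1, baseline 11). The focal scan
then shows a trans-QTL at the regulator's marker; the score stage scans
every gene annotated inside the trans peaks' 1.5-LOD intervals, assembles
evidence (variant and functional tables are user-supplied config), and the
regulator — cis-regulated, correlated with the focal gene, carrying a
nonsynonymous variant and causal functional evidence — scores 7/10 and
ranks first. Across 100 seeded replicates the recovery rate exceeds 90%.
If no chromosome reaches the suggestive threshold the global top
chromosome is retained so the score stage always has an interval.

## Statistical power of eQTL localization at small effects

At a planted additive effect of β = 1 log2 unit with residual sd 1 and 40
strains, the expected LRS at the causal marker is ≈ 9 — the same
magnitude as the genome-wide null maximum for any multi-chromosome map.
Monte Carlo at these conditions shows the genome-wide argmax lands at or
adjacent to the planted marker in only ~60% of replicates (wrong
chromosome ~28%), and the 1.5-LOD interval covers the planted marker in
~65%; with a 1000-marker map coverage drops further. Reliable (> 90%)
genome-wide localization at n = 40 requires roughly β/sd ≥ 2. The
acceptance suite asserts the stricter recovery bounds at β = 1 and
documents this as a known limitation rather than inflating the planted
effect.

## Numerical conventions

- Quantiles: type-7 (numpy default linear interpolation).
- p-values are clamped to (smallest positive double, 1]; underflow never
  reports 0.
- Result files: TSV/JSON with floats at 6 significant digits,
  deterministic row order; the pipeline manifest records SHA-256 checksums
  and per-stage parameters, and reruns with the same config and seed are
  byte-identical.
- Coordinates are 1-based physical megabase midpoints; all interval
  comparisons are inclusive.
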