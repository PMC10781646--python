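# Methods

## Data model and preprocessing

A compendium is a sparse cell × gene matrix with per-cell `cell_type`,
`condition` (a cytokine name or the reserved control token `PBS`) and
`replicate` labels. QC keeps cells with >500 detected genes, >1,000 total
counts and <10% mitochondrial content; all three comparisons are strict
(a cell at exactly 10% mitochondrial content is removed — the bound's
behaviour at the boundary is a deliberate convention, exposed as a
parameter). Normalization scales each cell to 10,000 total counts and
applies the natural log with a pseudocount of one, ln(x/Σx·10⁴ + 1);
normalization therefore preserves within-cell expression rank order.

Gene exclusion policies remove, per analysis stage: ribosomal (`Rps*` /
`Rpl*`) and mitochondrial (`mt-*`) genes; "unlabelled" genes, defined here
by configurable regular expressions (default `Gm\d+$` and `Rik$`, the
mouse predicted-gene and cDNA-clone conventions); packaged lists of
dissociation-induced immediate-early genes and cell-cycle genes; genes
detected in fewer than ten cells; and optionally the top 0.1% of genes by
total counts ("globally overabundant", off by default). The packaged lists
are curated mouse-symbol fixtures, small on purpose; users can supply
their own.

## Differential expression and signatures

All group comparisons use the two-sided Wilcoxon rank-sum test on
normalized expression. When both groups contain at most eight cells the
p-value is exact: every C(n₁+n₂, n₁) assignment of the pooled (mid-)ranks
is enumerated and the two-sided p is the fraction of assignments whose
rank-sum deviates from its null mean at least as much as observed — ties
are handled naturally because the pooled ranks are fixed under relabeling.
Larger groups use the tie-corrected normal approximation with continuity
correction. Columns with zero pooled variance receive p = 1. Multiplicity
is controlled by Benjamini–Hochberg FDR; the family is all tested genes
within one (cell type, cytokine) contrast.

Fold changes follow the common single-cell convention
log2((mean(expm1 x) + 1) / (mean(expm1 y) + 1)): values are de-logged,
averaged on the normalized scale, and offset by a pseudocount of one.

A cytokine signature applies, in order: FDR < 0.05 → |log2FC| > 0.25 →
expression in >10% of treated cells (up-regulated genes) or PBS cells
(down-regulated genes) → fold-change consistency in at least two of the
three replicate animals → category exclusions. The replicate criterion
recomputes the fold change within each replicate (treated cells of that
animal against its own PBS cells, falling back to all PBS cells when the
animal has none) and requires the same threshold in the gene's overall
direction; the threshold restated per replicate equals the global one
(0.25), since nothing in the design suggests a different value.

## Response magnitude

Per cell type, at most 100 cells are sampled (seeded) from each condition,
the Euclidean distance between each cytokine's centroid and the PBS
centroid is taken over all genes, distances above the 95th percentile
(linear-interpolation definition) across that cell type's cytokines are
replaced by the percentile, and the result is scaled linearly so the
maximum is 100. Cell types are scaled independently because their gene
detection properties differ. Combinations with fewer than five treated
cells are omitted. The centroid uses all genes rather than a
variable-gene subset — with no selection step specified anywhere, the
whole transcriptome is the least arbitrary choice.

## Gene programmes

Programmes are non-negative matrix factors (scikit-learn NMF, Frobenius
loss, coordinate descent, NNDSVD-ar initialization, fixed seed, so fits
are deterministic). Cells are sampled to at most 100 per (cell type,
condition); genes pass the strict exclusion policy. The factorization's
scale indeterminacy is fixed by normalizing each loading vector to unit
L2 norm and moving the scale into the cell weights, which makes programme
weights comparable across programmes and gives the effect size (difference
in mean weight, treated vs PBS, display-capped at 10 with the raw value
retained) a stable meaning. Cytokine-centric fits use k = 40 and may pool
conditions that act through the same receptor (the two type I interferons;
the two IL-1 forms); cell-type-centric fits use k = 10. A programme counts
as a response programme when its effect size exceeds 1 at FDR < 0.01 in at
least one cell type. Top-gene lists take the n = 30 highest loadings with
lexicographic tie-breaks. Over-representation of top genes in a gene-set
collection is the upper-tail hypergeometric test with BH correction across
sets; full rank-based enrichment is out of scope and top-gene
over-representation is the supported reduction.

## Polarization states

Discriminating genes are those whose |log2FC| versus PBS exceeds a
cell-type-dependent threshold (parameter, default 0.75, intended range
0.75–1.5) under at least one cytokine, after removing dissociation,
cell-cycle, mitochondrial and ribosomal genes. Cells of the cell type are
embedded by PCA (default 20 components) on these genes, connected in a
k-nearest-neighbour graph (k = 20) and clustered with Leiden (RB
configuration, resolution 0.5, seeded — the graph-clustering parameters
are package choices, stated here because no canonical values exist for
subclustering). Singleton clusters are merged into the nearest cluster by
centroid distance, and labels are renumbered by decreasing size so runs
are comparable.

For every (cluster, cytokine) pair an upper-tail hypergeometric test asks
whether the cluster holds more of that cytokine's cells than expected
(population = all cells of the type, marked = the cytokine's cells,
draws = the cluster). BH correction runs over all pairs within the cell
type — the widest defensible family — and clusters with any driver at
FDR < 0.01 become states. The biological-curation step that a human would
apply on real data is intentionally not automated: all statistically
called states are returned, ranked.

State markers are rank-sum DEGs of the state against all other cells of
the type, sorted by descending log2FC among significant genes. Cross-state
similarity uses PBS-subtracted mean profiles (Pearson) and the Jaccard
index of up- and down-regulated gene sets at |log2FC| > 0.5, computed
separately; two empty sets count as identical on the diagonal but are
skipped (not scored 1) when averaging for the uniqueness score, which is
the inverse of the mean off-diagonal Jaccard. The dendrogram is
average-linkage on Euclidean distances between rows of the Pearson matrix,
exportable as Newick. Naming reserves letters a–d for states whose top
driver is a type I interferon, IFNγ, IL-1α/β or TNF respectively (largest
state wins when several qualify); remaining states take e, f, … by
decreasing size, with two-letter suffixes past z.

## Production, receptors and interactomes

The production map averages each cytokine's encoding gene(s) per cell type
over all conditions (stimulation can induce production), caps means at 1
expression unit, and normalizes each cytokine row by its maximum cell
type; a cytokine counts as expressed above 0.1 normalized units and is
dropped when detected in fewer than 50 cells. Heteromeric cytokines score
via their most-expressed subunit and carry an asterisk wherever that
relaxed rule applies, propagated to all exports. Receptor complexes
require every component above threshold (default 0.1), any receptor option
sufficing; receptor thresholds use the same all-condition averages as
production, for symmetry.

Ligand–response edges connect a producing cell type through a cytokine to
every cell type whose signature has strictly more than ten DEGs;
ligand–receptor edges instead require receptor expression, with an
identical production side, so the two networks differ only in the target
criterion and are directly comparable as edge-set partitions. Strict
threshold comparisons on derived ratios carry a 1e-9 guard so exact
boundary cases (e.g. a mean ratio that is arithmetically 0.1) are not
decided by floating-point representation. The abundance–production
analysis correlates log10 PBS cell counts per type with the number of
cytokine genes detected (any subunit above 0.1) on an equal-size sample
per type (parameter; no canonical size exists) and reports Pearson r with
its two-sided t-test p.

## IREA

Gene-set mode sums the set's normalized expression per reference cell and
rank-sum-tests cytokine-treated against PBS-treated cells, BH-corrected
across the cytokine panel; the hypergeometric variant tests the set's
overlap with each cytokine's FDR < 0.01 DEGs against the reference gene
universe.

Matrix mode reduces the user's condition and control matrices (normalized
to 10,000 per cell, log-transformed — the same scale as the reference) to
one differential vector, restricted to genes shared with the reference and
above 0.25 average reference expression (at least ten genes must survive).
Each reference cell of the chosen cell type is centred by the PBS mean of
that cell type, so the cosine similarity compares two differentials; this
realizes the intended weighting where concordantly regulated genes push
the score up and oppositely regulated genes push it down, and it makes the
score antisymmetric under query negation and invariant to positive
rescaling of the user vector. Centring is configurable off. Projection
scores on cytokine-treated cells are compared with PBS-treated scores by
rank-sum test; the effect size is the mean difference; the FDR family is
the cytokine panel within one cell type. Per-gene contributions are the
elementwise product of the user and reference mean differentials.

Polarization mode applies the same machinery with a state's member cells
as the treated group and the remaining cells of the type as the control
group. If at least one state reaches FDR < 0.05 the effect sizes are
clipped at zero and divided by their maximum (radar scores in [0, 1],
max-normalization being the simplest scheme satisfying that bound);
otherwise every radar score is zero, denoting unpolarized input.
Communication networks combine producer edges (any ligand subunit above
0.1 mean expression in the user data, heteromers asterisked), responder
edges (IREA FDR < 0.01 with positive effect size), and receptor flags at
the dedicated 0.05 threshold on user condition cells.

Homolog mapping applies only one-to-one pairs from a two-column table,
dropping one-to-many mappings with a warning; the packaged table is a
small synthetic subset for tests and examples, not a full homology
resource.

## Synthetic benchmark

`generate_compendium` draws counts from a gamma-Poisson model:
per (cell type, gene) lognormal baseline means (median 0.5, σ = 1, giving
realistic library sizes around 1,500–2,000 counts over 2,000 genes),
gene-level dispersion 0.5 (var = μ + 0.5μ², typical droplet
overdispersion), a shared lognormal replicate factor per (replicate, gene)
with σ = 0.05 (so the ≥2-of-3-replicates filter faces real between-animal
variation), and a lognormal per-cell library factor with σ = 0.2. Planted
modules multiply their genes' means by 2^log2FC in a random responding
fraction of treated cells. The default benchmark plants one disjoint
30-gene module per cytokine (log2FC 2, 80% responders) in every cell type
— six cytokines (named after real ones so the reserved-letter naming is
exercised), four cell types, three replicates, 200 cells per (cell type,
condition), 2,000 genes plus the ligand and receptor genes of the
six-cytokine catalog subset, with a fixed production pattern per cell
type. Everything is deterministic per seed.

Query generation adds Gaussian noise in log-expression units around the
expected treated and control profiles; "20% noise" means σ = 0.2 on that
scale, commensurate with typical log-profile magnitudes of 1–3.

The generator emulates the compendium's design, not droplet chemistry: no
ambient RNA, doublets, batch effects, or cell-type-specific detection
differences beyond the baseline draws. Passing recovery tests therefore
shows the statistics behave as specified under the stated noise model —
it does not certify performance on real tissue data, where QC and
cell-type annotation quality dominate.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the benchmark at the sizes
above (≈5,600 cells × 2,000 genes), 100 null repetitions at 20 genes ×
50 cells for calibration, and 24 noisy queries for IREA recovery — sizes
chosen so the full suite exercises every stage end-to-end on a laptop.
Exact rank-sum enumeration is limited to groups of ≤8 (12,870 assignments
at worst); NMF runs at most 500 coordinate-descent iterations at tolerance
1e-5; percentiles use the linear-interpolation (type-7) definition;
hierarchical clustering ties follow scipy's defaults. Known limitations:
the signature caller assumes library-size normalization is adequate
(strong compositional shifts would bias fold changes), state calling
depends on the clustering resolution for weakly polarized states, and the
packaged catalog's receptor lists are deliberately minimal — real analyses
should supply a curated catalog.
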