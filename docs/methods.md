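# Methods

## The problem

Immune-stimulatory double-stranded DNA triggers two intertwined responses in
macrophages: a *direct*, cell-autonomous response in the cells that sense
cytosolic dsDNA (cGAS → STING → IRF3), and a much broader *indirect* response
driven by secreted type I interferons binding IFNAR on neighboring cells and
inducing interferon-stimulated genes (ISGs) through ISGF3.  Bulk assays
average the two.  The analysis implemented here dissects them with
single-cell RNA-seq and a condition contrast: when IFNAR is neutralized with
a blocking antibody, paracrine amplification is removed, so any cell that
still expresses ISGs must have sensed DNA itself.  The pipeline isolates
that rare ISG-positive population, places it within the macrophage subset
structure, and ranks the genes that discriminate direct from indirect
responders — with Ccl5 as the expected leading marker.

## Pipeline

The stages follow the standard droplet scRNA-seq toolchain, each exposed as
a library function and a CLI subcommand:

1. **QC** — retain cells with 200–2,000 uniquely detected genes (bounds
   inclusive) and < 1 % mitochondrial counts (strict); mitochondrial genes
   are identified by the murine `mt-` prefix, case-insensitively.  The
   filter is idempotent and errors rather than returning an empty matrix.
2. **Normalization** — each cell's counts scaled to a total of 10,000,
   then `ln(1 + x)`.  The linear stage's column sums equal 10,000 exactly.
3. **HVG selection** — 3,000 genes by variance-stabilizing transformation:
   a local quadratic trend (tricube weights, span 0.3) of log10 variance on
   log10 mean of raw counts, standardization by trend-predicted SD with
   clipping at √n_cells, ranking by the variance of standardized values.
   Ties break on the gene name so selection is deterministic.  HVGs are
   computed per condition dataset; integration features aggregate the
   per-dataset rankings (most-nominations, then best rank, then name).
4. **Integration** — canonical correlation analysis on the scaled shared
   features (top-k singular triplets of the cells-by-cells cross-product;
   paired embeddings row-L2-normalized, deterministic joint sign
   convention), mutual-nearest-neighbor anchors in CC space scored by
   joint-neighborhood overlap, and per-cell correction of log-normalized
   HVG expression by a Gaussian-kernel weighted sum of anchor difference
   vectors.  The largest dataset serves as reference and passes through
   unchanged.  Anchor filtering by HVG-space neighborhood (`k_filter`) is
   accepted in the config but deliberately inactive, and anchor scoring is
   shared-neighbor overlap rather than a rank-based score — both are
   documented simplifications of the method this stage re-implements.
5. **Clustering** — PCA (30 PCs, ARPACK, largest-loading-positive sign
   convention) on the z-scored corrected matrix, a shared-nearest-neighbor
   graph (k = 20 neighborhoods including self, Jaccard edge weights, edges
   below 1/15 pruned), and Louvain modularity optimization at resolution
   0.8, seeded.  UMAP exists for visualization only; no downstream
   computation consumes its coordinates.
6. **Phase assignment** — per-phase score = mean log-normalized expression
   of the marker pair minus a size-matched random control set (fixed seed);
   the call is the argmax with ties resolved S > G2 > G1.  The panel-phase
   map (Mcm5/Mcm6 → S, Top2a/Cenpa → G1, Birc5/Nusap1 → G2) follows the
   source study's own nomenclature even though Top2a/Cenpa are
   conventionally G2/M markers; the map is configuration.
7. **Scores** — ISG Score and Direct Score are per-cell sums of **raw**
   counts over fixed panels, divided by the cell's total counts and scaled
   by 10⁴ (bounded in [0, 10⁴]).  Raw counts, never corrected values, so
   scores are independent of integration.  The panel symbols `Gpb5`/`Gpb2`
   are kept as printed and matched through a logged alias map
   (`Gbp5`/`Gbp2`).
8. **Markers** — Wilcoxon rank-sum on log-normalized uncorrected
   expression with midranks, tie-corrected normal approximation with
   continuity correction (exact enumeration when a group has < 10 cells and
   the space is tractable), detection (`min_pct` 0.1) and fold-change
   (`logfc_min` 0.25) pre-filters, Bonferroni over the pre-filter gene
   count (BH by flag).

## Direct-responder isolation

Control and blocked datasets are integrated and reclustered.  A cluster is
flagged when its median ISG Score exceeds the pooled 95th percentile *and*
more than 80 % of its cells come from the blocked condition; flagged
cells from the blocked condition are the direct responders.  Both
thresholds are config (`direct.isg_quantile`, `direct.blocked_fraction`).

Anchor-based correction can absorb a rare population with no counterpart in
the reference into its host cluster (the rare cells anchor onto reference
cells and their distinguishing program is subtracted).  When no cluster
qualifies, a cluster-free fallback therefore applies the condition contrast
directly on raw-count scores: the control arm defines the null ISG-score
distribution, and a blocked cell is flagged when its score exceeds twice
the null's 99th percentile (and the pooled 95th).  A genuine direct
response sits many-fold above baseline, while a null tail does not reach
twice its own upper quantile, so a dataset with nothing planted yields zero
flagged cells.  The fallback additionally verifies the contrast premise
itself — the blocked arm's rate of score-high cells must exceed four times
the control arm's (with at least three such cells) — because "ISG-high
despite blockade" only identifies direct responders if the control arm
lacks such cells; with scrambled or meaningless condition labels the
procedure refuses rather than mislabeling generic ISG-high cells.  The
cluster-free Otsu thresholding of scores remains available separately as
`threshold_isg_positive`.

The host subset is named by marker voting on the flagged cells (mean
log-normalized Fabp4/Fabp5 and H2-Aa/H2-Ab1 expression against the pooled
mean), expected to read `Fabp4posMHCIIneg`.

For discriminant ranking, the flagged direct cells are combined with the
Fabp4⁺MHCII⁻ cells of the dsDNA-alone condition and the candidate list (the
18-gene ISG panel plus Cdk8, Cxcl2, Cd74; a user file is accepted) is
ranked by Wilcoxon differential expression without detection or fold
filters, so every candidate receives a rank; a `significant` column records
Bonferroni significance at 0.05 alongside the raw ordering.  The top four
genes form the Direct panel.  An alternative `--against isgneg` mode
contrasts the direct cells with the ISG-negative part of the combined
subset, with the ISG⁺/ISG⁻ split taken from the Otsu threshold on ISG
Score rather than from reclustering the combined subset — differential
testing runs on uncorrected data anyway, so re-integrating a ~20-cell
population would add fragility without changing the tested contrast.

## The synthetic-data generator

The generator is first-class, tested code that plants exactly the
population structure the analysis assumes, with full ground-truth labels.

**Count model.**  Counts are negative binomial, `var = μ + θμ²` with
`θ = nb_dispersion = 0.3`, sampled as a gamma–Poisson mixture.  Library
sizes are log-normal (`ln 4000 ± 0.35`).  A cell's mean vector is its
library size times a state-dependent composition: baseline gene abundances
(log-normal weights, σ = 1.7) times multiplicative folds for subset
programs, cell-cycle phase, condition response and sub-state, renormalized
to sum to one, with mitochondrial genes carrying a per-cell planted
fraction (0.4 % ± 0.2 %, clipped at 0.8 %).  `expected_mean` returns the
exact mean used for sampling and is checked against empirical means and the
NB variance law in the tests.

**Planted structure.**  Six BMDM subsets in fixed proportions (two
proliferating, 15 % each; Fabp4⁻MHCII⁻ 20 %; Fabp4⁺MHCII⁻ 25 %;
Fabp4⁺MHCII⁺ 15 %; S100a4/6⁺ progenitor 10 %), each with a private 30-gene
program at 6-fold plus its canonical named markers (Fabp4/Fabp5,
H2-Aa/H2-Ab1 with Cd74, S100a4/S100a6); proliferating cells carry a phase
(60/40 major/minor mix) with the paired phase markers elevated.  Ms4a7 is
highly expressed everywhere and never responds to condition, mirroring a
pan-macrophage marker.  Under dsDNA the ISG panel is induced 8-fold
uniformly in all subsets; under IFNAR blockade only the planted direct
responders (3 % of Fabp4⁺MHCII⁻ cells) are induced.  Direct responders
exist at the same fraction in the dsDNA arm — direct sensing precedes
amplification — and carry an extra 6-fold on Ccl5 in both dsDNA-exposed
arms, which is what makes Ccl5 discriminative.  A leaky IFNAR-KO arm
(scattered 5 % ISG⁺ cells, separately labeled) can be generated but is
ignored by the direct pipeline by default.

**Breadth of the IFN response.**  Induction is not limited to the 18 scored
ISGs: an extended response program of 120 low-baseline genes is induced
with the same folds, reflecting that ISGF3 upregulates hundreds of effector
genes.  This breadth matters quantitatively: a fold-8 shift restricted to
18 moderately expressed genes in a ~0.7 % subpopulation lies below the
Marchenko–Pastur noise edge of 3,000 z-scored HVGs at ~3,000 cells, i.e. no
PCA-based pipeline could find the rare ISG⁺ cluster the analysis is about.
Keeping the program genes at low baseline (weight 1.5 versus a median
background of 1) keeps the induced transcriptome mass near 6 %, so the
realized panel-level induction stays within 10 % of the planted fold
despite compositional renormalization.

**Condition-3 sub-states.**  With `condition3_substructure` enabled
(default), the blocked arm carries two extra sub-state splits of
non-proliferating subsets: Fabp4⁻MHCII⁻ divides into two states (a 30-gene
program at 6-fold distinguishing them), and Fabp4⁺MHCII⁻ divides into the
ISG⁻ bulk and the ISG⁺ direct responders.  Clustering the blocked arm alone
therefore yields eight planted groups, exactly one of them ISG-high.

**QC failures.**  5 % of cells are deliberate QC failures: high planted
mitochondrial fraction (3–12 %), or a tiny (~80 UMI) or huge (~50,000 UMI)
library; huge-library failures are only drawn when the gene universe is
large enough for them to exceed the 2,000-gene cap.  Every planted failure
violates at least one retention rule by construction.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: ambient RNA, doublets, batch chemistry
differences, UMI collisions, gene–gene correlation beyond the planted block
programs, continuous differentiation trajectories, and transcriptome-wide
compositional shifts larger than the planted ISG program.  Real tissue data
will also carry many more weakly variable genes, so HVG selection there
discards information in a way the 5,000-gene simulation cannot probe.

## Numerical and reproducibility choices

* All randomness flows from explicit integer seeds: the generator uses
  seed sequences spawned per condition; Louvain draws through Python's
  `random` module (seeded and restored around each call); ARPACK SVD gets
  a fixed deterministic start vector; PCA and UMAP receive fixed
  `random_state`.  A fixed config + seed reproduces reports byte-for-byte.
* CCA components are ordered by singular value, then sorted by realized
  canonical correlation (cosine of paired gene-space projections) so the
  reported correlations are non-increasing; each component's sign is fixed
  jointly (largest-|u| entry positive).
* Zero-variance genes scale to zeros, never NaN; degenerate UMAP input is
  jittered with a warning; an empty anchor set, empty QC result or absent
  panel raises with context rather than propagating empty arrays.
* Cluster labels are relabeled by decreasing size (ties by first
  occurrence), so label 0 is always the largest cluster.
* The phase-split merge used for coarse-subset counting tests every cluster
  pair over the integration features and merges a pair when all
  Bonferroni-significant DEGs between them are cell-cycle panel genes.

## Problem sizes

The shipped defaults simulate 3,000 cells per condition over 5,000 genes
(three conditions: 9,000 cells).  At that scale the full workflow —
generation, QC, per-condition HVG, pairwise CCA/MNN integration, PCA, SNN,
Louvain, phase assignment, scoring, one-vs-rest markers, direct-responder
isolation and ranking — completes in roughly a minute on one CPU; unit
tests run on 600-cell, 600-gene configurations of the same generator.

## Known limitations

* Anchor correction can still dilute rare unshared populations; the
  contrast fallback recovers them for scoring purposes, but the corrected
  embedding itself may not show them as a separate cluster at every seed.
* The Wilcoxon exact path enumerates rank assignments and is only engaged
  when a group is small and the assignment space is below ~2·10⁵;
  borderline sizes fall back to the tie-corrected normal approximation.
* Bonferroni over the pre-filter count is conservative by design (it
  matches the cited toolchain); BH is available but not default.
* The condition-contrast design cannot, even in principle, identify direct
  responders inside the dsDNA-alone arm; they are only recoverable under
  blockade.
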