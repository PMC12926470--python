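# Methods notes

## The synthetic data generator

The generator stands in for sorted CD45+ cells from three conditions
(healthy, LLC1, Kras) because the study's raw data are not publicly
archived.  It emulates exactly the features the downstream stages consume,
and nothing more.

**Count model.**  Counts are negative binomial via the gamma–Poisson
mixture, with a single global dispersion θ (default 2) so that
`var = μ + μ²/θ`.  Per-gene baseline means are log-normal across genes
(`ln μ ~ N(−0.7, 1)`), giving a median per-gene mean of ~0.5 counts and a
realistic detection profile (~700–800 detected genes per cell at the
default 2,000-gene universe).  Genes belonging to any marker program are
pinned to the central baseline (μ = e^−0.7) so planted signals never land
in the undetectable low tail.  A 13-gene mitochondrial block (named with
the mouse `mt-` prefix so the QC prefix rule finds it) is sized to
contribute 4% of each cell's counts in expectation — about 3.5 standard
deviations below the 8% QC cutoff, so essentially all clean cells pass
cell QC while the margin still leaves the QC rule something to reject when
failures are spiked in.

**Populations.**  Cells draw a subtype label from a per-condition
multinomial (`CompositionProfile`); the packaged profiles encode the
published per-condition compartment percentages and within-compartment
subset percentages (percentages are renormalized to sum to 1 where the
printed numbers sum to 97.8–100.1; the B-compartment plasma fraction is
the remainder to 100%, consistent with its description as "<1%").  Marker
programs shift the natural-log mean of their genes in the owning
population: 8-gene compartment panels and 12-gene subtype panels at a
boost of 2.0 (≈7.4-fold), and 3-gene condition programs at 1.2.  The
12-gene panel size is a separability requirement, not a tuning knob:
4-gene panels leave the subtype structure invisible in the first 6
principal components (the PCs are then dominated by high-mean baseline
genes), and the generator would fail its stated purpose of planting
transcriptionally distinct subtypes.  Each condition is split round-robin
into 3 pseudo-samples, standing in for the three mice per condition that
the real experiment pooled before sequencing; pseudo-sample structure
carries no extra variance component, because none is estimable from a
pooled design.

**What it does not model.**  Doublets, ambient RNA, batch effects, UMI
saturation, cell-cycle structure, gene–gene correlation beyond the shared
programs, and inter-mouse variability.  Passing recovery tests therefore
demonstrates that the pipeline's logic is correct under the stated
generative model — not that it is robust to the full messiness of real
scRNA-seq data.

## QC and normalization

Order is fixed: cell filter → gene filter → normalization, one pass, no
re-iteration.  Gene filtering can in principle push a cell's detected-gene
count below threshold afterwards; the one-pass order mirrors the original
bookkeeping, and each filter is idempotent at fixed input.  "Detected"
means raw count > 0.  The mitochondrial share is computed on counts (not
gene numbers), the 8% rule is strictly "greater than", and the 300-gene
rule strictly "fewer than".  The sex-gene list ({Xist, Ddx3y, Eif2s3y,
Uty, Kdm5d}) is configurable since no canonical list exists.  Highly
variable gene selection is deliberately not performed.  PCA runs on
centered (not scaled) log values with a deterministic solver; each
component's sign is fixed by forcing its largest-magnitude loading
positive, so repeated runs agree bit-for-bit.

## Clustering and annotation

The neighbor graph uses k = 15 neighbors (a conventional default; the
original text does not state k) on the first 6 PCs.  Leiden runs on the
UMAP-style connectivity graph with the RB-configuration objective at
resolution 0.5; labels are relabeled by decreasing cluster size for
run-to-run comparability.  The UMAP embedding is visualization-only — no
statistic in the package depends on it, and pipeline callers may skip it.

Marker ranking is a one-vs-rest Welch t-test (the unequal-variance form,
matching the behaviour of the common single-cell frameworks) with BH
correction per cluster's gene list.  The "fold change ≥ 0.5" filter is
read on the log2 scale, computed from de-logged group means with a 1e-9
pseudocount — a linear threshold of 0.5 would select depleted genes, which
contradicts the notion of a marker.  All three filter boundaries are
inclusive.

Annotation replaces manual curation with signature scores: cluster-mean
expression of each signature gene is z-scored across clusters (population
sd) and averaged over the signature; clusters take the argmax label, ties
broken lexicographically.  The sd in the z-score is floored at 0.05
log-expression units.  Without the floor, genes that are flat up to
sampling noise get inflated to full-size z-scores, and whenever Leiden
splits a dominant subtype across several clusters (which it routinely does
at resolution 0.5), the diluted true-marker scores can be beaten by noise,
mislabelling whole clusters.  Genuinely marked genes move cluster means by
an order of magnitude more than the floor, so their scores are essentially
unchanged.  Subclustering recomputes PCA, neighbors and Leiden on the
compartment subset with the same defaults (resolution 0.5; only the
top-level resolution is specified in the original text).

One caveat observed on synthetic data: community detection at a fixed
resolution does not guarantee "no structure → one cluster".  On a kNN
graph of identical points Leiden still partitions the (arbitrary) graph;
the no-structure property only holds for graphs without spurious sparsity,
e.g. disconnected cliques.

## Enrichment

The over-representation test is the one-sided hypergeometric upper tail
with the universe defaulting to all genes that survived QC (the
conservative choice; the original used an external web service whose
universe is unknowable).  BH adjustment is applied within each direction.
The directional integration rule — keep a pathway iff adjusted p < 0.2 in
exactly one direction — and the top-20 cap per contrast and direction
follow the study's procedure; ties order by raw p, then label.

## Interaction score

Each quoted ingredient maps to one factor: "z-score of the group mean
expression" → z across clusters (population sd, z = 0 when sd = 0),
"scaled by group size" → w = n_c/N, "weighted by the proportion of cells
expressing" → f.  The per-pair score is the sum of the ligand component in
the source cluster and the receptor component in the target cluster; the
per-cluster-pair total additionally sums over pairs, and both are emitted
because "sum of valid pairings" supports both readings.  Complexes take
the minimum component score and minimum expressing fraction over subunits
(limiting-subunit convention).  Validity defaults to "expressed by more
than 0% of cells in the cluster" for both units and is configurable.
Z-scores are computed within one condition at a time; the alternative
(across all condition×cluster groups) is equally defensible but couples
conditions, which would contaminate the differential step.  Quantile
ranks use average ranks for ties, normalized by the number of valid
interactions in that condition (max rank 1.0); interactions valid in only
one condition appear as gained/lost rather than receiving an undefined
rank difference.

## Proportion tests

Per-sample proportions get a Haldane-style continuity adjustment,
(count + 0.5)/(total + 1), before the logit — zero counts then stay
finite, and the adjustment direction is symmetric.  The default test is
the pooled-variance Student t (the classical "unpaired t-test"); Welch is
available via `equal_var=False`.  BH correction runs across cell types
within a condition pair.  With 3 pseudo-samples per condition the test has
4 degrees of freedom; the power and calibration checks in the test suite
run at that size.

## Problem sizes and determinism

Default study-scale runs use 3,000 cells per condition for compartment
recovery and 2,000 cells for compartment-restricted subtype recovery, with
a 2,000-gene universe — large enough that the 3-standard-deviation
multinomial envelopes around the published percentages are a few points
wide, small enough for interactive use.  All randomness flows from one
`numpy` Generator per stage, seeded explicitly; identical inputs and seeds
reproduce outputs byte for byte, including CSVs written by the CLI.

## Known limitations

- Cluster-level annotation assigns whole clusters; subtypes too rare to
  form their own Leiden cluster at resolution 0.5 (e.g. plasma cells at
  <1%, or ~3–5% subtypes at 2,000 cells) are absorbed by neighbors and
  report 0%.  That behaviour is faithful to cluster-then-annotate
  pipelines but understates rare populations.
- The enrichment stage tests discrete marker lists; ranked (GSEA-style)
  statistics are out of scope.
- The interaction score has no permutation null; scores are comparative,
  not calibrated p-values.
- The pseudo-sample proportion test exercises the statistics, but cannot
  resolve what constituted biological replicates in the pooled original
  design.
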