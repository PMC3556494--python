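# Methods

## Model and procedure

lnskit quantifies cross-species conservation of co-expression
neighbourhoods.  The pipeline is:

1. **Preprocessing** (`lnskit.io`).  Per dataset: genes observed in less
   than half of the arrays are removed (the 50% boundary itself is kept —
   removal applies to genes *below* the threshold); remaining missing
   values are estimated by K-nearest-neighbour imputation (K = 10,
   Euclidean distance); biological replicates are averaged.
2. **Connection matrices** (`lnskit.coexpression`).  All-pairs Pearson
   correlation per dataset, Fisher z-transform (arctanh), standardisation
   of the off-diagonal entries to mean 0, sd 1.  The global network is the
   entrywise average over datasets, re-standardised.
3. **LNS** (`lnskit.lns`).  Per ortholog pair, the Pearson correlation of
   the two species' connection vectors over the other N − 1 matched
   orthologs.  The null shuffles the B-side ortholog assignment uniformly;
   diverged genes are counted below the pooled null mean, with a two-sided
   Mann–Whitney U comparing real and null distributions.
4. **Periodicity** (`lnskit.periodicity`), **sequence-divergence
   association** (`lnskit.association`) and **profile clustering with
   enrichment** (`lnskit.clustering`) consume the preprocessing and LNS
   outputs.

Assumptions: expression values are log-ratios on a roughly continuous
scale; orthology is strictly one-to-one; datasets are exchangeable units of
evidence (the aggregate weights each dataset equally, not each array);
time-course datasets are evenly sampled.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_fraction` | 0.5 | minimum fraction of arrays a gene must be observed in; kept when exactly at the boundary |
| `k` (imputation) | 10 | neighbours averaged per missing cell |
| `clip` | 1 − 1e−6 | correlation clip before arctanh; keeps duplicated/self correlations finite while moving values by < 1e−5 in z space |
| `n_permutations` | 50 | null permutations; each contributes N pooled LNS samples |
| `seed` | 17 | default for every stochastic operation; all CLI randomness flows from `--seed` |
| `n_top` | required | periodic-call count; dataset-specific, so user-supplied (a 1% FDR helper, `suggest_n_top`, estimates it from time-permuted nulls) |
| `alpha` | 0.01 | Bonferroni-corrected enrichment threshold |

## Numerical and design choices

- **Standardisation statistics** use the finite off-diagonal upper triangle
  only: each unordered gene pair counted once, diagonal excluded.  The
  diagonal is stored as NaN so no downstream vector can pick up a
  transformed self-correlation.
- **Aggregation** re-standardises: an average of D independent standard
  normal matrices has sd 1/√D, so a final rescale restores the unit-sd
  guarantee.  Matrices are aligned on the union of gene universes; a pair's
  average runs over the datasets where both genes survived filtering, and
  pairs never co-observed stay missing (flagged downstream).
- **Connection vectors** exclude indices j and j′ from both species'
  vectors: the self-entry is a clipped, transformed 1.0 that would inflate
  every LNS.
- **Constant or too-short vectors** (fewer than 3 aligned finite entries,
  or zero variance) yield a missing LNS with an explanatory flag; they are
  excluded from counts and medians, and the exclusion count is reported.
- **The null keeps accidental self-matches**: the B-side permutation is
  uniform over all permutations, not derangements, mirroring the idea that
  randomisation disturbs only the ortholog match, never the networks.
- **KNN imputation** averages the k nearest neighbours unweighted;
  distances are computed on mutually observed arrays and scaled by
  √(total/shared) so sparsely co-observed genes are not spuriously near.
  Cells with no eligible neighbour fall back to the gene's row mean, then
  the column mean, with a logged count.
- **Zero-variance genes** get correlation 0 (hence z = 0) with a flag
  rather than removal, keeping matrices aligned across datasets.
- **Periodicity score** is |X(f*)|² divided by the gene's total
  positive-frequency power, so ranking reflects spectral concentration, not
  amplitude.  The dominant frequency is called low-confidence when its
  share of total power is below twice the uniform share (2/n_freq) — white
  noise sits at the uniform share, a genuine synchrony signal far above it.
  Phase is the within-cycle position of peak expression, in [0, 2π).
- **Overlap significance** of periodic calls uses the exact hypergeometric
  upper tail on the ortholog universe, with an optional label-permutation
  p-value as a cross-check.  (A t-test on an overlap count is not a
  well-defined statistic; the hypergeometric formulation is.)
- **Cluster count** uses the gap statistic (uniform-box references, the
  one-standard-error rule), with k always overridable.  Ties in k-means are
  resolved by scikit-learn's Lloyd implementation with 10 restarts; empty
  clusters are re-seeded internally.  Cluster centres are displayed in
  optimal-leaf-order of an average-linkage dendrogram, which in particular
  makes collinear centres come out monotone.
- **Feature normalisation** (dN/dS and relatives) drops nonpositive values
  before the log2 transform rather than pseudocounting, with a logged
  count; three-level TATA status is coded both-vs-rest by default (the
  one-vs-neither contrast is available).
- **Permutation p-values** are add-one smoothed: (hits + 1)/(n + 1).

## The synthetic generator

`lnskit.simulate` emulates a multi-dataset compendium: each gene belongs to
one of `n_modules` co-expression modules; per dataset, each module draws a
latent profile (one N(0, signal²) value per array) and a gene's value is
its module profile plus N(0, noise²) measurement noise, giving a
within-module correlation of signal²/(signal² + noise²) (≈ 0.67 at the
defaults).  Species B shares the module map except for a planted fraction
of orthologs reassigned to a different module — exactly the neighbourhood
change LNS measures.  Missing cells (Bernoulli) and replicate arrays are
injected on request.  Defaults: 300 genes, 10 modules, 6 datasets × 12
arrays per species, signal sd 1, noise sd 0.7, 5% missing, 10% divergent,
seed 17 — a desk-scale version of a few-hundred-array compendium.  The
time-course generator plants cosines of known phase at a chosen cycle count
among noise genes.

What the generator does **not** emulate: dye bias and spatial artifacts,
heavy-tailed noise, overlapping or hierarchical modules, condition-specific
module rewiring within a species, partial divergence (a planted gene's
neighbourhood is swapped wholesale), and uneven dataset sizes or quality.
Passing tests on these fixtures therefore establish the estimator's
correctness and calibration under block co-expression structure, not the
biological findings obtainable from real compendia; the published medians
and correlations for real two-yeast data depend on those data collections
and are out of reach at this scale.

Two properties of the synthetic conditions are worth knowing when reading
the tests.  A *fully* diverged ortholog's LNS is itself a draw from the
randomisation null, so roughly half of the planted divergent genes fall
below the null mean — the below-null count has near-perfect precision but
only ~50–70% recall of planted truth, and the cleaner readout is the
ranking (planted genes recovered with AUC 1.0 at the defaults).
And deeper aggregates give higher LNS, so within- versus between-species
comparisons are made at matched dataset counts.

## Problem sizes

Test fixtures and the acceptance script run at the generator defaults
(300 genes) or below; the pooled null uses 34–50 permutations (≥ 10,000
samples), chosen as the point where the null's mean and shape estimates are
stable to well under the decision thresholds.  The whole suite runs in
seconds; the method itself is O(N²) per permutation in the number of
orthologs and has no problem at genome scale (thousands of orthologs).

## Known limitations

- Strictly one-to-one orthology; paralog families must be resolved
  upstream.
- The aggregate weights datasets equally regardless of array count or
  quality.
- Pearson-based throughout; no rank or mutual-information variant.
- Uneven time sampling is not supported in the periodicity module.
- GO-style annotation structure is flattened: no DAG propagation, terms are
  taken as given gene sets.
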