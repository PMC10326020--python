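# Methods

## Model and assumptions

The pipeline assumes a linear map between two omics layers measured over
the same ordered conditions: `Y = β·X + δ`, with rows = analytes, columns =
conditions, and `β` sparse. It is appropriate for continuous, complete
matrices only (no missing values); count data are expected to arrive
already transformed to a continuous scale. Associations are statistical,
not causal: an edge means two analytes co-vary across the condition panel
after the shared preprocessing, nothing more.

## Preprocessing

1. **Variance filter.** Per layer, the `ceil(fraction·R)` rows of highest
   raw (unbiased) sample variance are kept, ties broken by input order.
   Default fractions are 0.20 for the targeted proteomic layer and 0.10
   for the sequencing layers, reflecting their feature counts. The filter
   is applied to values as given, before any centering.
2. **Column-center → row-center → row L2-normalize**, in exactly this
   order (the steps do not commute). This removes magnitude bias so the
   regression sees profile shapes, and drives the per-row offsets δ toward
   zero (after preprocessing, `max|δ| < 1e-6` is asserted on every
   synthetic run). Row normalization is unit Euclidean norm; unit-variance
   scaling would only change λ by a constant factor per row. Rows whose
   post-centering norm falls below 1e-10 (constant rows up to an offset)
   are dropped and reported rather than normalized into NaN.

One pass of this pipeline is **not** idempotent: row normalization rescales
rows individually and thereby destroys the column centering, so a second
pass changes the matrix (materially so for small row counts). The
guarantees that hold for any output are: every surviving row has zero mean
and unit norm.

## The per-row cross-validated lasso

* Objective: `RSS + λ·Σ|β|` — no `1/(2C)` prefactor. The scikit-learn
  coordinate-descent backend uses `α = λ/(2n)` internally; all reported λ
  are in the unscaled convention.
* λ path: geometric, 100 points, from `λ_max = 2·max_j |⟨x_j, y⟩|` (the
  smallest λ with an all-zero solution on centered data) down by a factor
  of 0.01 when conditions < predictors, 1e-4 otherwise (the glmnet
  convention).
* Selection: minimum mean CV squared prediction error over K = 4 folds,
  fold labels drawn as a seeded permutation of `0..K-1` repeated over the
  conditions. Ties take the larger (sparser) λ. The 1-SE rule is *not*
  used.
* The final fit at the selected λ runs on the full row; coefficients below
  1e-10 in magnitude are exact zeros. `λ = 0` falls back to the
  least-squares solution of the normal equations.
* Performance note: path solves skip per-call input validation (arrays are
  promoted to Fortran-ordered float64 once per row); at the small per-row
  problem sizes used here validation would otherwise dominate the solve.

## Ensemble and robust selection

The coefficient matrix is refit `n_replicates` times; the only stochastic
element is the CV fold assignment, with the seed for replicate *r*, row *k*
derived as `SeedSequence([master_seed, r, k])`. Results are therefore
bit-identical across reruns and across serial/parallel execution
(aggregation happens in fixed replicate order). An entry is retained iff it
was non-zero in at least `ceil(min_frequency·n_replicates)` replicates
(default frequency 0.5), and its consensus value is the mean over exactly
its non-zero occurrences. Signed values are averaged as-is; a
sign-consistency fraction is carried per entry as a diagnostic. The
production-scale replicate count for real datasets is 10,000; the tests and
the acceptance script use 50–100, which is where the frequency estimate
stabilizes at desk scale.

## Leave-one-group-out (LOGO)

A group's columns are removed from the *raw* pair, the remainder is
re-preprocessed (centering depends on which columns are present), and the
ensemble is rerun. The group-specific association list is the symmetric
difference of the FULL and LOGO robust supports, each record tagged
`full_only` or `logo_only` and weighted by the coefficient of the run it
exists in. Entries present in both supports are excluded regardless of
coefficient change — support membership, not magnitude, defines
group-dependence. FULL and LOGO runs use independent master seeds, recorded
in the output sidecars.

## Networks and ranking

Robust entries with |coefficient| strictly above a threshold become edges
of an undirected gene-level multigraph; analyte-level direction (Y ← X) is
preserved in the lossless `edge_tsv` export. Two named thresholds are
shipped: **display** (0.01) and **comparison** (0.1); the latter is the one
to use before biological interpretation (see Limitations). Nodes are gene
symbols and carry the set of contributing assays; distinct analyte pairs
mapping to the same gene pair remain parallel edges, and a gene measured in
two assays can carry a self-edge.

The gene weight is `α_k = (Σ incident |β|) / (n1·n2·n3)`, the denominator
being the product of the three layer sizes — constant per run, so the
ranking is normalization-invariant; it is kept so scores are comparable
across networks built from the same inputs. Self-edges contribute once.
An alternative mode takes the absolute value of the *signed* per-layer-pair
sums (`abs_of_sum`); it lets opposite-sign associations cancel and is off
by default. Ties rank alphabetically. Export formats: GSEA preranked
`.rnk` (headerless, two tab-separated columns, unique keys, descending),
Cytoscape `.sif`, GraphML, and the round-trippable edge TSV. All writers
emit `repr`-precision floats; all readers parse with round-trip precision,
so write→read→write is byte-identical.

## Shuffled-input null

Each row of each input matrix is independently permuted across columns:
marginals (hence row variances, hence variance-filter decisions) are
untouched, while the cross-analyte alignment the lasso exploits is
destroyed. `pre_selection` shuffles before the variance filter,
`post_selection` after. Matched real and shuffled ensembles share all
settings; the comparison reports robust-support sizes and the two-sample
Kolmogorov–Smirnov distance (with asymptotic p-value, via SciPy) between
per-replicate support-size distributions. Within-column and whole-matrix
permutation modes exist for sensitivity checks.

## Synthetic data

The generator draws `X` i.i.d. standard normal, a sparse `B` with `s`
non-zeros of magnitude `|b| ∈ [0.8, 1.2]` and random sign, and
`Y = B·X + ε`, `ε ~ N(0, σ²)` with σ = 0.1 — strong planted effects over a
realistic condition panel (default 24 conditions in six ligand-labelled
groups of four). Group-specific blocks add coefficients active only in one
group's columns. `random_block` places block entries on distinct rows
(lightly loaded first) and on predictor columns unused by the global
support: a group-specific regulator is modelled as a different analyte from
the globally active ones, and this placement also avoids a small-matrix
artifact (see below). Gene symbols are synthetic, with deliberate
many-analytes-per-gene and cross-layer collisions so node coalescing and
self-edges are exercised.

What the generator does **not** emulate: count-data noise (negative
binomial overdispersion), batch structure, correlated predictors beyond
chance, and — importantly — realistic layer sizes. Two desk-scale artifacts
follow from small matrices and are worth knowing about:

* **Column-mean coupling.** The column mean of `Y` is a `1/n_y`-weighted
  mixture of the predictor signals, so column-centering subtracts a shared
  signal component from every row. With thousands of rows (real data) this
  is the intended removal of a condition-level offset; with tens of rows it
  measurably distorts sparse rows. Consequently the true coefficient matrix
  of the *preprocessed* system is never exactly the planted `B`.
* **Detection ceiling for group-restricted effects.** An effect confined to
  a `c`-column group contributes at most a fraction `c/C` of a row's
  normalized energy, giving a detection statistic of order
  `√C·√(c/C) = √c` — independent of the panel size. Four-column blocks sit
  near the detection edge of 4-fold CV at any desk-scale panel, so
  group-specific recovery rates are intrinsically noisy at these sizes.

Passing tests on this generator therefore demonstrate mechanical
correctness (selection rules, differencing, aggregation, determinism,
formats) and directional behavior (planted positions dominate occurrence,
shuffling collapses support); they do not certify recovery rates on real,
paper-scale data.

## Problem sizes and runtimes

The test suite runs ensembles of 5–100 replicates on matrices between
3×4 and 20×50 analytes over 12–24 conditions; the acceptance script uses
the 20×50×24 reference conditions with 100 replicates and a 12×10×20
five-group design with 50 replicates for the LOGO check. These sizes keep a
full run on one CPU in the minutes range while leaving the frequency
threshold meaningful.

## Known limitations

* **The minimum-CV-error λ overselects.** On rows with strong signal the
  selected λ is small and the solution carries many small-magnitude extra
  coefficients. Because replicates differ only in fold assignment, those
  extras are largely data-deterministic and survive the ≥50% frequency
  rule (this matches the reference behavior of glmnet's `lambda.min` on
  identical inputs). Recall of planted structure is 1.0 in every synthetic
  configuration tested; support precision at desk scale is ~0.1. The
  magnitude thresholds (0.01/0.1) applied at the network stage are the
  method's own answer to this, and any interpretation should start from
  the thresholded network, not the raw robust support.
* Support-frequency selection cannot separate true associations from
  stable shrinkage-compensation artifacts; only magnitude can.
* The LOGO symmetric difference is a set operation at the frequency
  threshold; entries hovering near 50% occurrence flip in and out, so
  group-specific lists for borderline associations are noisy at small
  replicate counts.
* No missing-data support, no elastic-net/ridge variants, no GPU solver.
* Enrichment analysis itself (GSEA, Reactome, EnrichmentMap) is out of
  scope; the package emits the `.rnk`/`.sif`/GraphML inputs those tools
  consume. For GSEAPreranked on real data the original analysis settings
  were: classic weighting, 1000 permutations, no symbol collapsing, p <
  0.05 and FDR < 0.1 retention.
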