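# Methods

## Model and assumptions

`siggraph` models each cohort's nonnegative expression matrix as an additive
mixture of a small number of nonnegative rank-one programs (gene loadings ×
per-sample activities) and treats the columns of the NMF factor `W` as
candidate transcriptional programs ("signatures", with "exposures" as the
weights). Three assumptions drive the design:

1. **Rank ambiguity is intrinsic.** The right number of programs per cohort
   is unknowable in advance, so instead of selecting one rank the pipeline
   factorizes at every rank in `[kmin, kmax]` and pools all signatures. The
   cost is redundancy (near-duplicate signatures across ranks); downstream
   steps are designed to tolerate it — filtering and matching operate per
   signature, and an edge needs only one surviving representative per
   program.
2. **Only top genes carry identity.** Most exposure weight in a signature is
   noise; the genes that identify a program are the few hundred with the
   largest exposures. Cross-cohort similarity is therefore Jaccard overlap
   of top-N gene sets, not a correlation over all genes.
3. **Disease relevance is a property of sample activity.** A signature
   matters for a diagnosis when its per-sample exposures separate cases from
   controls after covariate adjustment, regardless of what its genes are.

## Pipeline stages and numerical choices

**Row-mean normalization** divides each gene row by its mean (target mean 1).
Rows with mean ≤ 1e−12 cannot be rescaled and are dropped with a warning.
Normalization is applied after all row/column removals. The operation is
idempotent and preserves the zero pattern of retained rows.

**NMF solver.** Multiplicative updates for the squared Frobenius objective,
which are monotone (the test suite checks non-increase with relative slack
1e−8 per iteration). Initialization is NNDSVDa (SVD-based, zeros replaced by
the matrix mean): deterministic, so the entire pipeline is reproducible
without averaging restarts; a seeded random init is available. Convergence:
relative loss change < `tol` (default 1e−5) or `max_iter` (default 500);
non-convergence warns and returns the best iterate. Denominators carry a
1e−12 floor, which also makes the all-zero matrix a clean fixed point.
Degenerate all-zero signatures are retained but logged; they cannot win a
top-N match meaningfully. Per-rank runs are independent (no warm starts), so
losses across ranks may occasionally invert at high ranks due to local
optima; the monotone-in-rank property is only asserted while the rank is
below the number of planted factors.

**Diagnosis filter.** One OLS fit per signature:
`exposure ~ 1 + 1[case] + covariates`, two-sided t-test on the case
coefficient, strict threshold p < alpha (default 0.05), no multiple-testing
correction — the retained-fraction-under-null ≈ alpha behaviour is the
intended semantics and is what the calibration tests verify. Categorical
covariates are dummy-coded against the lexicographically first level;
covariate columns collinear with the existing design are dropped (later
column loses) with a warning; rows with missing covariates are dropped
pairwise; zero-variance exposures return p = 1 with a degenerate flag.

**Top-N sets and RBH.** Top-N selection (default N = 1000; scaled runs use
smaller N of the same order as the planted program size) sorts by descending
exposure with ties broken by ascending gene label, making results
label-deterministic. Jaccard is computed on gene labels over the union of
the two cohorts' universes: genes measured in only one cohort simply cannot
intersect (an optional restriction to the common universe exists). Best hits
are computed per cohort pair, as in ortholog RBH, so one signature may
connect to several cohorts; exact Jaccard ties keep all tied mutual bests;
zero-Jaccard candidates are discarded.

**Permutation edge test.** Within every signature the assignment of exposure
values to gene labels is shuffled (preserving each signature's exposure
multiset; a whole-matrix shuffle is available), top-N sets and RBH edges are
recomputed, and this repeats `n_permutations` times (default 20). An edge's
occurrence probability is `(1 + c) / (1 + n_permutations)`, retained when
≤ `edge_alpha` (default 0.05) — with 20 permutations exactly the edges with
c = 0. If `1/(1 + n)` exceeds `edge_alpha` the configuration is rejected
with the minimum usable `n`.

What counts as an occurrence is configurable, and the default is a
deliberate design choice. Counting a round only when the *identical
signature pair* re-links (`occurrence="same_pair"`) looks conservative but
is miscalibrated in both directions at small scale: a specific pair re-links
by chance with probability ≈ 1/(n_a+n_b−1) per round regardless of how
strong the observed edge was, so with ~30 signatures per cohort a genuinely
planted edge is discarded in ~30 % of runs, while weak chance edges are
retained whenever their pair happens not to recur. The default
(`occurrence="stronger_link"`) instead asks how often *any* chance RBH link
between the same two cohorts forms with Jaccard ≥ the observed edge's — the
observed best-hit strength is compared against the null distribution of best
chance-link strengths, which matches the conditioning under which the
observed edge was found (it too is a best hit). In measurements this retains
planted edges in 10/10 seeded studies while retaining 0 edges across 20 null
studies; the same-pair and any-pair counts remain available, and at full
scale (hundreds of signatures per cohort) the readings nearly coincide
because chance re-links become vanishingly rare.

**Edge taxonomy.** Same disease → `single`; same class, different disease →
`intra_class_comorbid`; different classes with exactly one psychiatric
endpoint → `inter_class_comorbid`; different non-psychiatric diseases →
`somatic`. The psychiatric class set defaults to {PSY}; class codes outside
the known set raise an error. Tissue relation is equality of endpoint
tissues.

**Gene categorization and ranking.** For a disease pair (a, b), the union of
shared genes over a–b edges is partitioned by membership in the unions over
a–a and b–b edges: a-only → `disease_a_specific`, b-only →
`disease_b_specific`, both → `shared`, neither → `distinct`. Gene symbols
are upper-cased before any set operation. Process genes are ranked by
√(exposure_a · exposure_b) per edge; a gene occurring in several edges keeps
its maximum geometric mean (a single ranked list needs one number per gene;
the maximum preserves "top responsive", and the source edge is reported).
Exposures are the row-mean-normalized W values without further rescaling.

**Enrichment.** One-sided hypergeometric upper tail per term, terms
intersected with the measured-gene universe and filtered to sizes
[10, 2000] by default; query genes outside the universe are dropped with a
warning; BH adjustment is applied per edge (per enrichment run), matching a
per-pair analysis; the full table is always returned with a significance
flag at adjusted p < 0.05. Overlap 0 gives p = 1 exactly.

**Knowledge-graph queries.** Edges are undirected and unweighted for path
purposes; relation strings are annotations. `neighborhood` is a multi-seed
BFS cutoff; `process_bridge` is the induced subgraph on the union of all
shortest paths from a process node to each of two disease nodes, warning and
omitting an unreachable half. The connectivity depth is a parameter
(default 3; a depth of 5 is equally defensible for wider context maps, and
both appear in practice).

## Synthetic data: what it does and does not emulate

`simulate.generate` builds each cohort as
`background + Σ_f w_f h_fᵀ`, then multiplies by lognormal noise
`exp(σZ)` and clips at 0. Per-gene background is Uniform(0.5, 1.5) — the
data are meant to resemble row-mean-normalized intensities, so baselines sit
near 1. A factor's gene loadings are `exposure_scale · Uniform(0.5, 1.5)` on
its signature genes and 1 % of that scale (Uniform) elsewhere, so top-N
recovery is a genuine inference problem rather than a support read-off.
Sample activities are Uniform(0.5, 1.5) on the factor's active group (cases,
controls, or all samples) and exactly 0 elsewhere. Covariates (age uniform,
sex Bernoulli) are independent of factors by default; a coupling flag adds a
factor's activity into a covariate to exercise confounder adjustment.

Defaults define the benchmark conditions: 4 cohorts (two PSY, two T2D; two
tissues per class), 2000 genes, 20 cases + 20 controls per cohort, 150-gene
disjoint factor blocks, `exposure_scale` 10 and noise σ = 0.5 (signal-to-
noise scale ratio 20), one case-active factor shared between one PSY and one
T2D cohort, plus per-cohort private case factors and always-on tissue
factors as nuisance structure. The null design keeps only the tissue
factors. The generator does *not* emulate probe-level artifacts, batch
effects correlated across cohorts, heavy-tailed single-gene outliers, or
correlated gene–gene noise — so passing recovery tests demonstrates the
pipeline's logic and calibration under its own model class, not performance
on raw microarray data.

## Problem sizes used in tests

The acceptance-style checks run the full pipeline at kmax = 8 (35 pooled
signatures/cohort), top-N 300 and 20 permutations on the 2000-gene 4-cohort
designs — 10 seeded studies for planted-edge recovery and 20 for null
calibration — and complete in a few minutes on one CPU. Unit tests use
smaller matrices (tens to hundreds of genes). These sizes were chosen so the
whole suite iterates quickly while keeping sample-to-gene ratios and
signal-to-noise in a realistic regime.

## Known limitations

- NMF is non-convex; NNDSVDa gives reproducibility, not global optimality.
  Pooling across ranks mitigates single-run fragility but near-duplicate
  signatures inflate node counts.
- The diagnosis filter's uncorrected p < 0.05 deliberately admits ~5 % false
  signatures per cohort; the permutation edge test is the stage that removes
  their chance associations.
- With 20 permutations the smallest attainable occurrence probability is
  1/21 ≈ 0.048, so `edge_alpha` meaningfully below 0.048 requires more
  permutations.
- Jaccard on label sets ignores exposure magnitudes beyond the top-N cut;
  programs of very different sizes can be under-matched at a fixed N.
- Edge categories depend on user-supplied disease/class codes; no ontology
  reasoning is performed.
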