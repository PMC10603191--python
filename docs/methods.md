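# Methods

This note documents the models, the numerical choices and the places
where the design was genuinely open, in the order the pipeline runs.

## Differential expression

Each gene is fit with a two-group linear model on log2 intensities and
moderated by empirical-Bayes variance shrinkage. The prior (d₀, s₀²) is
estimated by the method of moments on log residual variances: with
z_g = log s²_g and e_g = z_g − ψ(d/2) + log(d/2), the excess dispersion
var(e) − ψ′(d/2) determines d₀ through the inverse trigamma (solved by
Newton iteration), and s₀² follows from the mean of e. When the excess
dispersion is non-positive, d₀ = ∞ and every gene receives the pooled
variance (the t reduces to a z-test). A unit test cross-checks the
whole stage against the Bioconductor limma implementation on a shared
matrix (agreement to 1e-6 relative on t and p).

Choices: tests are two-sided; duplicate gene symbols collapse to the
record with the smallest p; the three selection thresholds default to
p₁ = 0.01, p₂ = 0.001, p₃ = 0.0001 and must be strictly nested, which
makes the per-threshold selections nested as well. Genes constant
across all samples with no shrinkage available get t = 0, p = 1 and a
warning rather than an error. Multiple datasets are analyzed separately
and merged by union with occurrence counts; no cross-dataset batch
correction and no pooled-p meta-analysis are attempted — the merge is
deliberately by occurrence frequency, occurrences/n_sources ∈ (0, 1].

## GO similarity

Wang S-values use edge weights 0.8 (is_a) and 0.6 (part_of), the
GOSemSim defaults. S(anchor) = 1 and S(t) = max over children c of t on
paths toward the anchor of w·S(c), computed by memoized traversal of
the anchor's ancestor closure; a brute-force path-enumeration oracle
verifies it on small DAGs to 1e-12. Term similarity is the shared-
closure sum over the two semantic values; BMA gene similarity averages
row and column maxima of the term-term matrix, so a gene against itself
is exactly 1.

The pairwise statistic M_simsc = ½(δ₁²/δ₂² + δ₂²/δ₁²)·((μ₁+μ₂)/2)² uses
each gene's similarity-row mean and sample SD (ddof = 1) with the
self-entry excluded — including the diagonal 1 would inflate every
row mean. The variance-ratio factor is ≥ 1 by AM–GM with equality iff
δ₁ = δ₂, so the statistic is smallest-possible for equally dispersed
rows and rewards pairs that are strongly and comparably connected to
the cohort. SDs are floored at 1e-8 to keep constant rows finite. This
particular combination of row statistics is one of several defensible
readings of the pairwise design; the components (means, SDs, the ½
factor, the pairwise double loop) are all exercised, and the statistic
is isolated behind `m_simsc` so an alternative reading is a one-function
change.

Genes lacking annotations in the requested namespace are dropped from
the matrix (logged), not zero-filled: a zero row would poison every
other gene's row statistics. Similarity defaults to the biological_process
namespace; MF/CC matrices can be built the same way but are not combined
into a single number.

## Score combination

M_expr is −log10 p, min-max normalized per dataset (|t| is available by
flag); it is the one expression quantity every upstream configuration
guarantees. M_simsc is reduced to a per-gene scalar by the row mean of
the pairwise matrix so the combination is well-typed. The cohort sizes
n_expr and n_sel act as channel weights; they can be overridden for
merged cohorts. Doubling both rescales the combined score but leaves
the min-max-normalized final score unchanged. Frequency enters
multiplicatively on the normalized score (additive behind a flag), so a
gene seen in every source keeps its score and a gene seen once is
discounted. When all combined scores are equal, min-max normalization
maps them to 1.0 rather than 0/0.

## Clustering

Features per gene default to (final, m_expr, m_simsc, frequency) —
clustering the 1-D final score alone is degenerate. Features are
z-scored, making the partition invariant under affine rescaling of any
input feature. Ward linkage on Euclidean distance is cut at k; the
resulting centroids seed a hand-written Lloyd loop that stops when the
assignment no longer changes (max 300 sweeps). The loop records the
within-cluster sum of squares per iteration, asserted non-increasing in
tests; empty clusters keep their previous center. k defaults to 4, or
is chosen by mean silhouette over a candidate range with ties going to
the smallest k. Manhattan and correlation distances are available for
the hierarchical stage; the refinement always minimizes squared
Euclidean distortion.

## Enrichment

Upper-tail hypergeometric only (over-representation; depletion is not
tested). Annotations are ancestor-propagated before counting, so a
parent term's annotation count dominates each child's. Benjamini–
Hochberg q-values are computed within each cluster by default (pooled
across clusters by flag). The hypergeometric tail and the BH step-up
are both verified against exhaustive-enumeration / from-definition
oracles.

## Prioritization

S_p(i,t) = μ₀(i,t) + Σ_j μ_j(i)·X_j(i): tissue mean expression plus the
per-category products of mean occurrence frequency and normalized
evidence value. The raw sum is the default ranking object — the
components are kept on their native scales because the downstream
interaction score needs S_p > 1 for log-positivity and because the
score should reduce to μ₀ when no category evidence exists. When
component scales are incommensurate, `standardize=True` z-scores μ₀
(per tissue) and each category contribution (across genes) before
summation; standardized scores are for ranking only and are not fed to
the interaction stage. Missing entries contribute 0 with a warning.
Ranking is per tissue, descending, ties broken by gene id.

Tissue membership is a separate multinomial logistic layer over the
standardized per-tissue score profile (optionally augmented with one-hot
cluster labels), trained on a seeded 60/20/20 split with labels
defaulting to each gene's argmax tissue. Degenerate inputs (one tissue,
or identical profiles) return the uninformative uniform answer instead
of fitting.

## Interaction

The normalized MGTI reading divides the mean log10 prioritization score
by log10 of the cohort maximum. It is the only form that satisfies the
declared (0, 1) range for scores above 1: the raw additive form
(mean log + log max) exceeds 1 whenever any S_p > 10, and is kept only
behind `normalized=False`. The score is strictly increasing in each
argument, symmetric, and reaches 1 exactly when both genes attain the
cohort maximum.

Band cutpoints: increased regulation is a closed-from-below decision at
0.31; [0.1, 0.31) is reduced regulation; below 0.1 is flagged as
inconsistent with upstream selection rather than silently labeled. With
the published band edges at 0.3 and 0.31, the sliver (0.30, 0.31) must
be assigned somewhere; assigning it to the reduced band keeps the
increased-regulation boundary at the printed 0.31 cutpoint and makes
the bisection over `classify_band` land there exactly.

Pair scoring scopes: "all" and "cluster" use each gene's maximum S_p
across tissues; "tissue" pairs genes within each tissue at local
scores. Scores ≤ 1 raise unless an explicit `sp_floor` > 1 clips them.

## Warehouse

Embedded SQLite, DDL shipped as `schema.sql`. One fact table carries
both row kinds (prioritization rows with a NULL gene2, interaction rows
with a NULL tissue) under a natural-key unique index, so reloading the
same outputs is idempotent. Dimensions use surrogate integer keys with
unique-indexed natural attributes. `validate_integrity` checks foreign
keys (PRAGMA foreign_key_check), natural-key uniqueness, and that every
stored band equals `classify_band` of its stored score. Loads are a
single transaction and roll back entirely on violation.

## Synthetic data

The generator defines the study conditions the tests run under:

* Expression: i.i.d. Gaussian noise (sd 1.0) on log2 scale around a
  N(8, 1) per-gene baseline; DE genes (default 5% of 2000) get a fixed
  mean shift (default 2.0; the parameter-recovery suite uses 3.0 with
  10 samples per group) in the last group. One linear model per gene,
  matching the DE stage's assumptions. No negative-binomial count model
  and no probe-level structure: the generator emulates an
  already-normalized matrix, and "Gaussian on log scale" is a stand-in
  for a distribution the normalized-input contract leaves unspecified.
* Ontology: preferential-attachment DAG per namespace (~60/20/20
  BP/MF/CC), new terms attach to 1–2 earlier terms with probability
  ∝ 1 + degree, depth capped (default 5), edges 80% is_a / 20% part_of.
  Acyclicity and root-reachability hold by construction and are
  asserted.
* Annotations and evidence: each of 4 ground-truth clusters owns a
  shared term pool; genes draw from their pool with probability 0.6
  (else the full vocabulary), so within-cluster similarity exceeds
  between-cluster similarity by construction. Tissue mean expression is
  uniform on [2, 5) with +6 in the gene's tissue of origin — strictly
  above 1 so prioritization scores stay log-positive. Default tissues:
  kidney, urine, immune_system, blood, embryonic_dev.
* Determinism: every product draws from a named stream seeded by
  (seed, crc32(stream name)), so outputs are byte-identical across
  processes for a fixed seed.

What passing tests show — and don't: recovery and calibration results
demonstrate correctness of the machinery under the generator's
idealized conditions (independent Gaussian genes, clean cluster
structure, complete annotation). They do not demonstrate robustness to
correlated genes, batch effects, annotation bias or heavy-tailed
intensities, none of which the generator emulates.

## Problem sizes and tolerances

Calibration uses 20 replicates of 2000 genes (5 vs 5), parameter
recovery 2000 genes (10 vs 10, 5% DE at effect 3); oracle equivalences
run on DAGs of ≤ 8 terms and universes of ≤ 12 genes where exhaustive
enumeration is exact, with agreement required to 1e-12. The inverse
trigamma stops at relative step 1e-8; min-max normalization of a
constant vector returns 1.0; similarity-row SDs floor at 1e-8; the
band bisection stops at interval width 1e-6 and reports 3 decimals.

## Known limitations

* Single-factor, two-group contrasts only; no covariates in the linear
  model.
* The gene×gene similarity matrix is dense O(n²) with per-pair term
  matrices — fine for funnel-selected cohorts (tens to hundreds of
  genes), not for whole transcriptomes.
* Evidence categories are assumed pre-normalized to [0, 1]; the package
  does not harmonize heterogeneous external databases.
* The interaction score depends on the cohort through its maximum S_p,
  so scores are comparable within a run, not across runs.
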