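# Methods

This note documents the statistical procedures, their assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Characteristic-direction differential expression

**Model.** Given log-scale expression for two classes (n₁ control, n₂
perturbation samples; at least two each), the characteristic direction is
the unit normal of the hyperplane that best separates the classes under
regularized linear discriminant analysis. Writing Σ for the pooled
within-class covariance and Δμ = μ_perturbation − μ_control,

    b ∝ Σ̃⁻¹ Δμ,   Σ̃ = (1 − γ)·Σ + γ·ν·I,   ν = tr(Σ)/r,

normalized to ‖b‖₂ = 1. A positive b_g means the gene is higher in the
perturbation class. The LDA view emphasizes a gene's direction of change
relative to the other genes over its marginal magnitude.

**Computation.** With genes ≫ samples, Σ is singular; the solve is done in
the span of the globally centered data. The data are projected onto the
right-singular directions with numerically nonzero singular values
(r ≤ n₁ + n₂ − 1). Because both the within-class scatter and Δμ lie inside
that span and the shrunken operator block-diagonalizes with respect to it,
the reduced solve is *exactly* the dense gene-space solve, at O(n_samples³)
cost; the test suite verifies this equivalence against an independent dense
implementation to 1e-8. Keeping the full numerical rank (rather than the
within-class degrees of freedom n₁ + n₂ − 2) is what preserves the
class-mean-difference component and makes the equivalence exact.

**Shrinkage γ** (default 0.5, range [0, 1]) blends Σ with the scaled
identity ν·I, where ν is the average eigenvalue. γ = 0 is raw LDA and can
fail on degenerate data; γ = 1 reduces to the (scaled) class mean
difference. The normalized direction is invariant to overall expression
scaling. The default is the midpoint because no principled value exists for
arbitrary data; it is exposed in `ChdirConfig`.

**Per-gene significance.** The CD statistic itself carries no per-gene
test. Significance here comes from a permutation null on the per-gene class
mean difference m_g — the gene-space quantity whose multivariate alignment
the CD coefficient measures. All class-size-preserving label permutations
are enumerated when the space has at most `n_permutations` elements
(default 1000; e.g. C(6,3) = 20 for a 3 vs 3 design), otherwise sampled
with replacement from a seeded generator; the observed labeling and its
mirror are excluded so the null is not contaminated by the tested signal.
Permuted mean differences are pooled across genes into a single null
sample, and p_g is the two-sided normal tail of |m_g| at the null's
standard deviation.

Two alternatives were implemented and rejected after measurement:

- *Empirical tail of pooled permuted |CD coefficients|* (+1 pseudocount).
  The unit-norm constraint forces |b_g| ≈ G^(−1/2) for G genes and the null
  floor 1/(1 + null size) cannot pass Benjamini–Hochberg at α = 0.01 for
  realistic G; at the generator's default conditions zero genes were ever
  significant, making the downstream enrichment stage vacuous.
- *Normal tail on pooled permuted CD coefficients.* Calibrated, but the
  normalization spreads ~half of the direction's energy over null genes at
  these sample sizes, leaving too little per-gene resolution (0–6
  significant genes of 50 planted per seed).

The mean-difference permutation null is calibrated (on pure-noise data the
fraction of nominal p < 0.05 stays within binomial 99% bounds of 0.05 — both
a unit test and an acceptance-script quantity) and recovers 14–27 of 50
planted genes per seed with ≈ 0 false positives at the default conditions.
Pooling the null across genes assumes comparable per-gene noise, reasonable
for log-scale expression; strongly heteroskedastic data would need a
per-gene studentization this package does not implement.

Nominal p-values are Benjamini–Hochberg adjusted (step-up; delegated to
`statsmodels.multipletests`, with the naive step-up kept as an independent
test oracle). A gene is significant at adjusted p ≤ α (default 0.01); the
signature splits into up = {b_g > 0, significant} and down = {b_g < 0,
significant}; zero coefficients join neither set.

## Enrichment-vector analysis

Each query gene set (the up or the down genes of a signature) is tested
against every term of a GMT-backed library over a declared background
universe N (default: the library's gene union — the paper-style tools never
publish their universe, so the smallest defensible one is used; it is
overridable). Query genes outside the universe are dropped with a warning.

Per term with K member genes and overlap x against a query of size q, the
p-value is the hypergeometric upper tail P(X ≥ x) (scipy's stable survival
function; verified against exhaustive combinatorial enumeration for all
N ≤ 30 to 1e-12). Terms are ranked by ascending p with lexicographic
tie-breaks, and the combined score is

    c = ln(p) · z,   z = (rank − μ_rank) / σ_rank,

where μ_rank and σ_rank are the term's expected rank and its spread under
random queries. Both good signals — small p and much-better-than-expected
rank — make c large and positive; a term with p = 1 scores exactly 0.

**Rank calibration** is Monte-Carlo: `n_draws` (default 300; the unit tests
use as few as 60, the symmetric-library check 1000) uniform query sets are
drawn from the background, all terms ranked each draw, and the per-term
mean/SD recorded. σ_rank is floored at 0.1 to avoid dividing by a
near-constant rank. Calibrations are bucketed by query size rounded to the
nearest multiple of 10 so a collection re-uses a handful of calibrations
instead of one per query. All draws are seeded; identical seeds give
identical calibrations.

Only the top 50 terms by descending c are retained per query. The
collection-level matrix has two columns per signature (`id|up`, `id|down`),
rows the union of retained terms, zeros elsewhere. Up and down columns are
kept separate and unsigned; whether a display merges them is a rendering
decision out of scope here.

## Compound matching

Cosine similarity s = ⟨v, u⟩ / (‖v‖‖u‖) between the query's full
coefficient vector and each library compound vector, restricted to the
intersection of the query's genes with the library's gene space (a real
L1000-style library never shares the query's exact gene space). Matches are
skipped with a warning when the overlap is below `min_overlap` (default 10)
or either restricted vector has zero norm. The cosine distance d ∈ [0, 2]
and s = 1 − d ∈ [1, −1] are equivalent; this package reports s. The full
vector (not only significant genes) is used by default because cosine on
sparse thresholded vectors is unstable at small overlaps.

Mimickers are the top 50 compounds by descending s among s > 0; reversers
the top 50 by ascending s among s < 0; s = 0 joins neither list; ties break
by compound id. Negating the query swaps the two lists with negated scores
*exactly* (floating-point negation is sign-symmetric), which the tests
assert without tolerance. The collection matrix holds the signed
similarities (positive mimic, negative reverse, 0 absent).

## Aggregation, PCA, clustering, report

The gene × signature matrix outer-joins the signatures' coefficient vectors
over the union of genes; a zero cell means "no change" (the gene is absent
from that signature). Every stored coefficient appears unchanged
(conservation is a property test). Row filters: *sum of change* keeps the
`top_n_per_tail` most positive and most negative row sums (both tails, ≤ 2n
rows, default 10 per tail); *variance* keeps the top n by row variance.
Ties break by row label; brute-force sort oracles back both filters.

PCA treats signatures as observations and genes as features, mean-centered,
not variance-scaled (coefficients are already on a common unit-norm scale;
scaling would inflate near-constant genes). The top three components are
kept; with fewer than three signatures the missing components are
zero-padded with a warning. Component signs are fixed by making the
largest-magnitude gene loading positive, so coordinates are reproducible.
A collection of identical signatures centers to zero and maps to the
origin with zero variance explained. The implementation (scikit-learn) is
checked against a full SVD oracle to 1e-8 up to per-component sign.

Heatmap row/column orders come from average-linkage agglomerative
clustering on cosine distance (zero-norm vectors get distance 1 to
everything), the default behavior of the interactive clustergram tools this
emulates. Vectors are pre-sorted by label before clustering so the ordering
is a function of the labeled data, not of input order.

`build_report` runs everything — optional signature-id subset (custom
report), optional metadata-field categories for the PCA points, gene-matrix
filter, enrichment matrix, compound matrix, clustering — and writes a JSON
manifest plus three TSV matrices (12 significant digits, round-trip-stable).
Two runs with the same inputs and seed are byte-identical except the
manifest's timestamp field.

## Synthetic data and what passing tests show

`fixtures.make_expression` emulates the typical deposited study: per-gene
baseline means N(8, 1) (log₂-like scale), i.i.d. Gaussian cell noise
N(0, σ), 3 control vs 3 perturbation samples, and additive shifts ±δ for
planted genes (half up, half down, exercising both tails). Defaults
δ = 3, σ = 1, 50 planted of 1000 genes. `make_library` plants one term
containing all planted genes among uniform random decoy sets;
`make_compound_library` plants a noisy copy and a noisy negation of a base
signature among random unit decoys (noise SD 0.1, 200 decoys).
`make_collection` runs independent generated datasets through the full CD
pipeline (200 genes, 20 planted per signature by default — smaller than the
single-dataset default to keep whole-collection runs cheap). All generators
are bit-reproducible given a seed.

The generators deliberately omit probe-level artifacts, batch effects,
heteroskedastic noise, correlated genes and platform differences. Passing
planted-recovery tests therefore demonstrates the *algorithms* recover
signal under the stated noise model — not that real cross-study collections
are free of confounding; the aggregation views exist precisely to make such
confounding visible.

## Numerical choices and degenerate inputs

- SVD rank tolerance: s₁ · max(m, n) · ε (the standard matrix-rank rule).
- Hypergeometric p clipped to [1e-300, 1] so ln(p) stays finite.
- BH inputs validated to (0, 1]; the permutation p floor keeps p > 0.
- Empty up/down query → empty (zero) matrix column with a warning, not an
  error; subset selecting zero signatures or an unknown metadata field → an
  error naming the available choices.
- All tie-breaks (ranks, orderings, top-k lists) are lexicographic, making
  every pipeline output a deterministic function of data + seed.
- Matrix TSVs are written with 12 significant digits; read-after-write
  reproduces values at that precision.

## Known limitations

- Ortholog and probe maps are plain TSV inputs; no identifier validation
  beyond uppercasing is attempted, and unmapped symbols are dropped (with
  counts) rather than guessed.
- The pooled permutation null assumes approximately exchangeable per-gene
  noise scales.
- Rank calibration cost grows with library size × n_draws; the bucketing by
  query size is a coarse approximation to per-size calibration.
- Cosine matching on very small gene overlaps is noisy; `min_overlap` only
  guards the floor, it cannot make 10-gene overlaps informative.
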