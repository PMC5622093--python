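# Methods

This note documents the statistical procedures implemented in `rsmp`, the
choices made where the design was genuinely open, and the limits of what the
synthetic validation shows.

## Data model and filtering

A dataset is four tables keyed by `sample_id`: the wide family × sample
abundance matrix (colonial taxa presence-coded 0/1), per-sample factors
(survey, gear, sieve, date, coordinates, depth, treatment, whether colonials
were recorded, whether the sediment sub-sample came from the same grab
deployment as the fauna), a long-format particle-size table
(`aperture_mm`, `percent` retained), and per-sample environmental variables.

Two filtered subsets feed the analyses:

* **Faunal subset** — 0.1 m² grabs sieved over 1 mm mesh; non-macrofaunal
  taxon columns (fish, diatoms, parasites, zooplankton, seeds, eggs; the
  match list is configurable) are dropped. Samples with and without colonial
  taxa are retained for coverage.
* **Sediment subset** — Hamon 0.1 m² gear; sediment data present and from
  the same deployment as the fauna; total percentage within 100 ± 1; no mass
  on the sample's largest sieve ("top sieve empty": otherwise still-coarser
  material might have been retained had a larger sieve been used); not
  flagged impacted; colonial taxa recorded.

Rules apply in a fixed order with first-match attribution, so per-rule
removal counts plus retained always reconstruct the input count, and both
filters are idempotent. Impact flags derive from dredging-exposure records:
a station is `impacted` iff it was dredged and the years since last dredging
are below the predicted recovery time of its seabed landscape; never-dredged
stations are `reference`; samples without exposure records stay `unknown`
(excluded from envelopes, kept in the table).

Raw sieve apertures collapse onto 12 standard classes (64, 32, 16, 8, 4, 2,
1, 0.5, 0.25, 0.125, 0.063 mm + pan) under retained-on semantics — an
aperture maps to the largest standard aperture not exceeding it — and the
standard classes aggregate to Wentworth fractions with lower-inclusive
intervals: S/C < 0.063; fS [0.063, 0.25); mS [0.25, 0.5); cS [0.5, 2);
fG [2, 4); mG [4, 16); cG [16, 64); cobbles ≥ 64 mm. Published sieve/class
tables are typographically ambiguous about which sieves feed fine vs medium
gravel, so the mapping is a data-driven table the user can override; the
defaults above are our documented assumption. Both steps conserve mass to
1e-9. Cobbles are excluded from the 7-vector used for testing but retained
in summaries so totals still close.

## Clustering

Faunal clustering runs on fourth-root-transformed abundances (down-weights
dominant taxa; leaves 0/1 colonial presences unchanged), physical clustering
on log(x+0.1)-transformed (SPM, Depth, Stress) then z-scored environmental
variables. The k-means uses MacQueen updates: after an initial assignment,
samples are visited one at a time and both affected centres are recomputed
immediately whenever a sample moves; convergence is a full pass without
moves (cap 100 passes). An emptied cluster is re-seeded at the sample
farthest from its current centre. Each fit takes the best of `n_restarts`
(default 25) initialisations by within-cluster sum of squares (WSS) and is
deterministic given its seed.

**Initialisation.** Restarts are seeded with k-means++ (distance-weighted)
sampling rather than uniform row sampling. With realistically uneven group
sizes, uniform seeding rarely places a centre in small groups and the
best-of-restarts solution can sit in a local optimum with several times the
WSS of the true partition; distance-weighted seeding removes this failure
mode at no cost to determinism.

The elbow curve reports (k, WSS, explained = 1 − WSS/TSS). Each k is
additionally warm-started from the previous best solution's centres plus the
worst-fitting sample, which guarantees explained variance is non-decreasing
in k. k itself is an operational choice — the default 12 faunal / 10
physical balances biological detail against per-group replication for the
sediment envelopes; the elbow plot is a guide, not a test.

Group relatedness is summarised by a group-average (UPGMA) dendrogram over
inter-centre distances (Euclidean by default; Manhattan — the "absolute
distance across all variables" reading — is available). Presentation codes
(A1, A2a-style) come from cutting this dendrogram at half its maximum merge
height for broad-group letters, numbering members in leaf order; they are
cosmetic over the integer labels. New samples are assigned to the nearest
centre (ties to the lowest group index) — the property that makes a centroid
method, rather than hierarchical clustering, usable for ongoing monitoring.

## Community statistics

Richness is the count of families present, abundance the summed counts
(colonials contribute 1), with dataset-wide average ranks for relative
"heat" mapping. SIMPER decomposes the average within-group Bray–Curtis
similarity exactly over taxa (for samples i, j:
S_ij = Σ_t 200·min(y_it, y_jt)/Σ_u(y_iu + y_ju)); per-taxon terms are
averaged over all within-group pairs and expressed as percentages of the
group mean similarity, and the characterising set is the smallest
descending-sorted prefix reaching 50 % (ties broken alphabetically for
determinism). SIMPER runs on the same fourth-root matrix as the clustering —
the similarity form; for within-group characterisation the dissimilarity
form selects the same taxa. Group summaries report min/mean/max/sd and a
tertile arrow per measure: the full range of *group means* is split into
three equal-width bands (↑ top, → middle, ↓ bottom); a degenerate range
(single group) reports ↑. Temporal faceting by 5-year bin × meteorological
season is a pure partition of the sample set.

## Explaining faunal structure

Predictors are pruned by iterated variance-inflation factors: VIF_j =
1/(1 − R²_j) from OLS of each variable on all others (intercept included);
the single worst variable above 2.5 is dropped and VIFs recomputed until all
pass, with alphabetical tie-breaks so perfectly collinear sets (e.g. the
closed gravel/sand/mud trio) resolve deterministically. Remaining skewed
variables (SPM, Depth, Mud) get log(x+0.1), then all are z-scored
(zero-variance columns are reported as errors rather than silently kept).
Analyses run on a balanced random subsample (equal n per faunal group,
seeded) to avoid dominance by large groups.

BIOENV searches predictor subsets exhaustively (combinatorial guard above 20
variables): for each size it reports the subset whose Euclidean resemblance
maximises the Spearman rank correlation ρ with the faunal Bray–Curtis
resemblance over the lower-triangle entries (average ranks on ties), and
flags the overall best.

PERMANOVA follows the direct McArdle–Anderson decomposition: with
A = −D²/2 Gower-centred to G, the SS of a model is tr(H G) for the hat
matrix H of the intercept-plus-predictors design; terms enter sequentially
(Type-I, matching the R convention of the era) and each term's SS is its
increment. p-values use free permutation of sample rows,
p = (b + 1)/(n_perm + 1) (default n_perm = 999 in the library, smaller in
the desk-scale pipeline default). R² components sum to 1 exactly by the
trace identity. With semi-metric dissimilarities (Bray–Curtis) G is not
positive semi-definite and individual sequential terms can carry slightly
negative SS — a known property of this partition, shared with R's adonis —
so per-term non-negativity is only guaranteed for metric distances.

## Sediment envelopes

For each faunal and faunal–physical group, the envelope over its reference
(filter-passing, non-impacted) samples is the columnwise mean x̄ and the
unbiased (n − 1) covariance Σ of the 7 Wentworth fraction percentages. A
group needs `min_n` (default 30) samples; smaller faunal–physical groups are
topped up with whole sibling physical groups of the same faunal code, in
cophenetic-proximity order along the physical centre dendrogram, with
provenance recorded. The default of 30 is our choice of a minimal covariance
sample; no published threshold exists.

Exactly closed compositions make the rows of Σ sum to ~0 — the matrix is
near-singular along the all-ones direction — and nothing here repairs that;
the change test handles it downstream.

MVDISP is rank-based: all within-group Bray–Curtis dissimilarities (on the
fraction percentages — our interpretation of the dispersion index, whose
exact formula is not restated in the monitoring literature we mirror) are
pooled and jointly ranked; a group's dispersion is its mean rank rescaled so
the pair-count-weighted mean over groups is 1. Values above 1 mark
internally variable groups; the index is invariant to duplicating samples.

Cumulative curves are running fine-to-coarse sums of the per-class mean
percentages, ending at the mean sample total. Textural descriptions follow
the conventional gravel–sand–mud ternary thresholds (gravel ≥ 80 % gravel;
30–80 % sandy/muddy gravel by the sand:mud ratio at 9:1 and 1:9; below 30 %
a sand/mud/muddy-sand name with "gravelly", "slightly gravelly" (< 5 %) and
"v slightly gravelly" (< 1 %) modifiers).

## The sediment-change test

Given a monitoring sample v and its group envelope (x̄, Σ, n):

* D² = (v − x̄)ᵀ Σ⁺ (v − x̄), where Σ⁺ drops eigenvalues below 1e-8 × λ_max
  (the relative tolerance absorbs the compositional null direction; the
  effective rank is reported — 6 for exactly closed 7-fraction data).
  Perturbing v along a null direction does not change D².
* p = P(χ²_rank ≥ D²), the large-n reference: with n = 948 in the reference
  example the finite-n correction is negligible, and in one informative
  dimension the rule reduces to |v − x̄| > 1.96 σ at α = 0.05. A finite-n
  variant (T² = D²·n/(n+1), F = T²(n−r)/(r(n−1)) ~ F(r, n−r)) is available
  behind `method="hotelling"`.
* verdict: `favourable` iff p ≥ α (default 0.05).
* diagnosis: diff = v − x̄ (reported to 0.1 percentage point), %diff =
  100·diff/x̄ (reported to integer %, undefined where x̄ = 0); the drivers
  list orders fractions by |diff| among those whose contribution
  diff_i·(Σ⁺diff)_i to D² is positive.

Batches apply the test per station with no multiplicity adjustment by
default — a failure triggers further investigation, not a formal family-wise
claim; Benjamini–Hochberg is available behind a flag. Monte-Carlo
calibration: for samples drawn from a multivariate normal matching the
envelope, the rejection rate at α = 0.05 sits within two binomial standard
errors of 0.05 over 2,000 replicates. Real sediment compositions are not
multivariate normal (they are non-negative and closed); the chi-square p is
an approximation whose field-data behaviour remains an open question, which
is why failures are flagged for investigation rather than treated as proof
of impact.

## Gravel–richness regression

Richness (or total abundance) is regressed on % gravel by ordinary least
squares with Survey as a factor: one intercept per survey, a common slope.
Richness values are high enough (mean ≈ 30 in the data this mirrors) that
normal errors are an adequate approximation, and the survey factor absorbs
the residual lag-1 autocorrelation that a pooled fit shows (samples within a
survey are more alike); the autocorrelation is computed with samples ordered
by survey then input order — our documented choice. Fits are reported
per faunal group and overall, with p < 0.001 stars and the median survey
intercept for plotting. Mixed-effects alternatives and
autocorrelation-robust errors are out of scope.

## Synthetic data: what it emulates, and what passing shows

The generator builds a multi-survey dataset (default 20 surveys × 30
stations, 12 assemblages over 150 families of which 20 are colonial, 10
physical groups, ~8 % impacted stations, 70 % of surveys recording
colonials) with planted truth for every stage:

* **Population vs sampling.** Population structure — physical-region
  centroids, assemblage geometry, taxon pools, sediment signatures — comes
  from a private fixed-seed generator: as with a real regional baseline,
  there is one "nature", and replicate datasets are independent samplings of
  it. The config seed drives only station placement, counts and noise.
* **Assemblages.** Group identity follows a soft rule on three drivers —
  current speed and latent mud/sand tendencies, weighted per the configured
  effect sizes (defaults 6.1 : 3.0 : 4.0 for AvCur : Mud : Sand) — via
  nearest-anchor assignment with noise; anchors are centroids of a k-means
  partition of the weighted driver space, keeping groups balanced. Counts
  are negative-binomial (size 5, overdispersed as grab data are) around
  fourth-root-space centroids; each group carries 16–36 characteristic
  families (more for gravel-rich groups, so richness rises with gravel
  *across* groups), and bands of families respond unimodally along each
  driver gradient so faunal similarity is graded, not flat, between groups.
  The station-level niche response acts on the current axis only, keeping
  within-group richness independent of gravel — the construction the
  regression analysis is meant to detect.
* **Environment.** Realistic shelf scales with the collinearity that
  motivates VIF pruning: temperature tracks latitude, chlorophyll tracks
  SPM, bed stress tracks current speed, and gravel/sand/mud are closed to
  100 so the trio is exactly collinear (the alphabetical tie-break removes
  Gravel, mirroring practice).
* **Sediments.** Logistic-normal compositions per faunal(–physical) group —
  chosen over Dirichlet so realistic negative off-diagonal covariances
  arise — with inflated silt/clay noise (the most measurement-variable
  fraction), emitted as full 12-class sieve ladders with totals jittered
  within ±0.6 %, plus a handful of planted filter violations (bad totals,
  mass on the top sieve) recorded in the truth.
* **Surveys and impact.** Per-survey detection thinning shifts richness
  between surveys; impacted stations carry a +2.5-logit fine-sand
  enrichment and exposure records consistent with their flags.

On these defaults: k-means at the planted k recovers the partition
(ARI ≥ 0.9, typically 1.0), the elbow explains > 0.70 at k = 12, BIOENV's
best subset contains AvCur and Sand in ≥ 90 % of replicate datasets,
PERMANOVA detects the planted drivers while null predictors reject at the
nominal rate, and pooled gravel–richness slopes are positive while
within-group slopes centre on zero. Passing these checks shows the
*machinery* is correct and well calibrated under its own assumptions. It
does not show that field data meet those assumptions: real assemblages are
a continuum rather than separated clusters, real sediment compositions are
not multivariate normal, spatial autocorrelation is absent from the
generator, and real environmental layers carry interpolation error. The
published dataset-level values (best-subset ρ, adonis partitions, per-group
composition tables) depend on the deposited field data and are not
reproduced by synthetic runs; the structural analogues above are.

## Numerical choices

* Pseudo-inverse tolerance 1e-8 × λ_max; zero effective rank is an error.
* Mass-conservation and closure identities asserted to 1e-9; WSS
  consistency to 1e-8.
* k-means ties (equidistant centres) resolve to the lowest index; SIMPER
  ties alphabetically; VIF ties alphabetically; augmentation ties by lower
  physical-group code.
* Permutation p-values use the (b + 1)/(n_perm + 1) estimator, never zero.
* Report rounding: differences to 0.1 percentage point, percentage
  differences to integers; internal arithmetic is full precision.
* The desk-scale pipeline default (`rsmp run`) uses 10 restarts, 199
  permutations and a balanced subsample at the smallest group size; library
  defaults are 25 restarts and 999 permutations.
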