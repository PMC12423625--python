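# Methods

## The model

`hesrank` treats a cross-national assessment as a decision matrix
`G = [g_ij]` of m alternatives (countries) by n criteria (indicators),
scores bounded on the indicator scale (0–100 for GHSI data, enforced
only when a matrix is flagged GHSI-scaled — the engine is generic).
Three stages turn `G` into an ordered five-tier classification, and a
fourth compares runs across periods and regions.

### Entropy weighting

Column shares `n_ij = g_ij / Σ_i g_ij` define a proportion distribution
per criterion; its normalised Shannon entropy
`Ent_j = −(1/ln m) Σ_i n_ij ln n_ij` lies in [0, 1], and weights are
normalised divergences `W_j = (1 − Ent_j) / Σ_k (1 − Ent_k)`. The
weighting is purely dispersion-driven: a criterion on which all
countries score alike has entropy 1 and weight 0.

Conventions and edge cases:

* `0·ln 0 := 0` — scores of exactly 0 are legal (GHSI sub-scores hit 0).
* A column summing to 0 (or containing negative scores) is an error,
  not silently dropped: it signals bad input, and the share
  distribution is undefined.
* An all-constant matrix raises a no-information error rather than
  returning uniform weights; the weight formula is 0/0 there and any
  fallback would be an invention.
* Weights are computed independently per (region, period) dataset.

Invariants verified by tests: weights sum to 1 (±1e-9) and are
non-negative; scaling any column by a positive constant leaves all
weights unchanged (shares cancel the constant); permuting countries
changes nothing; a mean-preserving spread of a column never lowers its
weight.

### CoCoSo ranking

Min-max normalisation is direction-aware (`(g−min)/(max−min)` for
benefit criteria, reversed for cost criteria) so 1 is always best. A
constant column normalises to 1 for every alternative — the neutral
choice for a non-discriminating criterion in both the additive sequence
`S_i = Σ_j w_j r_ij` and the exponential sequence `P_i = Σ_j r_ij^{w_j}`
(with `0^0 := 1` so a zero-weight criterion contributes 1 uniformly).

The three appraisal scores are

    k_a,i = (P_i + S_i) / Σ_i (P_i + S_i)
    k_b,i = S_i / min S + P_i / min P
    k_c,i = (λ S_i + (1−λ) P_i) / (λ max S + (1−λ) max P)

with λ = 0.5 by default (configurable in [0, 1]; at λ = 0.5, `k_c` is
symmetric under exchanging S and P). `min S = 0` or `min P = 0` — an
alternative worst on every criterion — makes `k_b` undefined; this
raises by default, with an optional ε-floor (1e-12) because silently
inflating `1/min` distorts `k_b`. Note `Σ k_a = 1` and `k_b ≥ 2`
always, while `max k_c = 1` holds exactly when one alternative
maximises S and P simultaneously (the usual case; `k_c ≤ 1` always).

The composite is the canonical CoCoSo aggregation
`C_i = (k_a k_b k_c)^{1/3} + (k_a + k_b + k_c)/3`; a literal
"arithmetic-only" variant `(Σk)^{1/3} + (Σk)/3` is kept behind a
`variant` switch purely for auditing other implementations. Ranks are
descending in `C`; exact ties are broken alphabetically and flagged,
since any deterministic rule suffices but must be visible.

Tests check every intermediate against a plain-loop transcription
oracle at 1e-12 on random instances, plus dominance preservation: a
country at least as good on every criterion (strictly on one) never
ranks below the country it dominates.

### Tiering

Clustering operates on the one-dimensional composite scores `C_i`, not
the raw indicator vectors (a multi-dimensional mode would be a
different analysis; the composite is what the tiers summarise). In 1-D
the sum-of-squares-optimal K-means partition is contiguous in sorted
order, so the default solver computes it exactly by dynamic programming
over segment boundaries (O(K m²) with prefix sums) — deterministic,
with no initialisation to be sensitive to. A Lloyd/k-means++ solver
(default seed 42, 100 restarts) is kept for parity-checking against
conventional K-means tooling; it can never beat the DP solver's
within-cluster sum of squares and agrees with it exactly on separated
data.

Tiers are numbered by strictly descending centroid: 1 High, 2 Safe,
3 Intermediate, 4 Warning, 5 Dangerous ("Alert" and "Moderate" accepted
as aliases). K = 5 is the default; selecting K is out of scope.

Validation uses the silhouette coefficient
`s(i) = (b(i) − a(i)) / max(a(i), b(i))` with Euclidean distance on the
score line; points in singleton clusters get `s(i) = 0` (common
convention). The implementation is checked against
`sklearn.metrics.silhouette_samples`.

A caveat worth stating plainly: published tier tables produced with
initialization-sensitive K-means tools can be *local* optima. For the
bundled published composite scores, the printed partitions have
strictly larger within-cluster sums of squares than the DP optimum in
all three periods, so the optimal solver reproduces their extreme tiers
but legitimately disagrees at some middle-tier boundaries (e.g. it
places Monaco's 2019 score with the Dangerous group, as the study's own
summary does). The mean silhouette across the three printed period
partitions evaluates to 0.57; per-period values are 0.56, 0.59 and 0.56
(printed partitions) versus 0.58, 0.62 and 0.59 (optimal partitions).

### Comparison analytics

* **Weight deltas**: late minus early, per indicator; full-precision
  deltas sum to 0 exactly, deltas recomputed from 3-d.p. printed tables
  sum to 0 within ±2e-3 and match printed change tables within ±0.001
  (printed tables difference unrounded weights).
* **Rank shifts**: improved = rank number strictly decreased, declined
  = strictly increased, stable = unchanged; percentages are
  `100·count/m` at full precision, rounded only for display.
* **Tier profiles**: unweighted means of sub-indicator scores over tier
  members, one row per tier level.
* **Regional comparison**: tidy (region, period, indicator, weight,
  delta) table, chart-ready.

## Synthetic data

The generator emulates the shape of a GHSI-style dataset — default 27
countries × 6 benefit indicators in [0, 100], optional 34-column
sub-indicator panel — with the two statistical features the pipeline
responds to:

* **Dispersion control.** Column j is drawn as
  `lo + (hi−lo)·Beta(μκ_j, (1−μ)κ_j)` with concentration
  `κ_j = 1/dispersion_j` and common mean μ = 0.55. A mean-and-
  concentration parameterisation was chosen because the scores are
  bounded and the concentration directly controls the dispersion that
  entropy weighting rewards: larger dispersion ⇒ lower entropy ⇒ larger
  weight, which tests confirm at m = 200.
* **Planted tiers.** Tier k's countries score `Normal(μ_k, σ)` on every
  indicator, truncated (clipped, not rejection-sampled — simpler, and
  the bias is negligible at the tested σ) to the bounds. Default test
  conditions: μ = (90, 70, 50, 30, 10), σ = 2, sizes (3, 7, 8, 5, 4) —
  tier gaps of 20 points = 10σ, comfortably above the ≥4σ separation at
  which exact recovery is expected. Ground-truth labels are returned
  beside the matrix, never embedded in it.
* **Sub-indicator panels** attach each sub-indicator to a parent
  indicator (round-robin) and add bounded uniform noise, so tier
  profiles inherit the planted ordering.

What passing on this generator does *not* show: real GHSI columns are
neither beta-distributed nor independent across indicators, real tier
structure is far less separated than the planted one, and country
scores correlate across editions. The generator establishes
correctness of the machinery (recovery under honest separation,
invariances, determinism), not real-world discriminating power.

## Numerical choices

* Entropy values are clipped to [0, 1] to absorb ~1e-16 summation
  excursions; weight sums are exact to 1e-9.
* CSV writing renders floats at `repr` precision, so read(write(m))
  round-trips bit-for-bit and repeated runs are byte-stable.
* The published 3-d.p. weight tables are admitted into `WeightVector`
  (sum tolerance 2e-3 at the type level); freshly computed weights are
  held to 1e-9 by the tests instead.
* DP tie-breaks: with equal-cost splits the DP keeps the first optimum
  found (smallest left segment); labels are order-isomorphic to values.
* The silhouette denominator `max(a, b) = 0` (coincident points across
  clusters) yields s = 0.

## Problem sizes

The test suite and the acceptance script run on the bundled 27-country
printed tables, random instances up to 8×4 (ranking) and n ≤ 12
(clustering versus exhaustive search), dispersion checks at m = 200,
and 27×6 planted-tier pipelines; everything completes in seconds.

## Known limitations

* The aggregated multi-year matrix is the unweighted cell-wise mean of
  the edition matrices; sources that pre-aggregate differently should
  supply the aggregated matrix directly (the aggregation method is a
  config field).
* Published weight tables for other regions are ingested as data;
  recomputing them requires their raw matrices, which are not bundled.
* Reproducing published *local-optimum* tier tables is out of scope on
  principle: the exact solver is deliberately initialization-free.
* No treatment of missing scores: matrices must be complete.
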