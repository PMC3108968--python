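# Methods

## Data model

The input is a complete three-way rating design: `n_experts` raters score
`n_parties` objects on `n_policies` integer 1–20 scales, plus one 1–20
left–right ideology scale per (expert, party).  Party-by-party
dissimilarities for expert k are Minkowski distances between policy-rating
profiles,

δ_k(i, j) = ( Σ_c |r_kic − r_kjc|^{p_in} )^{1/p_in},

with the ideology column always excluded.  How the original analysts derived
their dissimilarities from the ratings is not recorded; profile distance is
the conventional choice, and because the downstream fit is nonmetric (rank
order only), the choice of `p_in` matters little.  The default is the
Euclidean profile distance `p_in = 2`; `p_in = 1` and the dominance
(max-component) sentinel are equally supported.  The constraint matrix R is
the element-wise mean of the expert matrices.

## Loss

For each expert the fitted configuration X (n_parties × q) minimizes

S(X) = σ₁²(X; Δ_k) + λ σ₁²(X; R)

where σ₁²(X; D) = Σ_{i<j} (d̂_ij − d_ij(X))² / Σ_{i<j} d_ij(X)² is squared
Kruskal stress-1, d(X) are Minkowski-p distances of X, and d̂ are monotone
disparities: the isotonic least-squares fit of the current distances
against the rank order of D (pool-adjacent-violators;
`scipy.optimize.isotonic_regression`).  Both terms share the Σ d² 
normalizer, so λ weighs two quantities on the same scale; λ = 100 makes the
average-structure constraint strong but not hard — solutions may, and do,
trade some constraint violation for expert fit.  Ties in the integer-valued
dissimilarities are handled by the primary approach (tied dissimilarities
impose no order constraint); the secondary approach (ties forced equal) is
available via `EngineSettings(ties="secondary")`.

Reported stress is always *exact, unpenalized* stress-1 of the final
configuration against the expert's own data, recomputable from the
configuration alone; the penalized smoothed loss is only the optimization
vehicle.  No post-hoc rotation is ever applied.

## Optimization

City-block stress surfaces are riddled with non-differentiable local
minima.  Three devices are combined:

1. **Distance smoothing.**  |t| is replaced by a Huber-style surrogate
   h_τ(t) = t²/(2τ) + τ/2 for |t| < τ (equal to |t| outside), and smoothed
   distances d_τ = (Σ_m h_τ(e_m)^p)^{1/p} are annealed over a geometric
   ladder of 16 levels, τ₀ = median off-diagonal dissimilarity, ratio 0.7,
   final level exactly τ = 0.  A broad ladder proved essential: with a
   narrow one (τ₀ = median/10, 10 levels) the attained penalized loss on
   the bundled Germany data was measurably worse (0.0537 vs 0.0481) and
   synthetic self-consistency fits stalled an order of magnitude above the
   reachable stress; the broad ladder recovers the generating metric in
   20/20 replicate surveys in each direction.

2. **Majorization.**  At loss value S₀, any decrease of
   G(X) = numerator(X) − S₀ · denominator(X) (zero at the current point)
   strictly decreases the ratio S.  With disparities fixed, G is
   Σ a d² − 2 Σ b d + const with a = 1 + λ − S₀ > 0 and
   b = d̂_E + λ d̂_R ≥ 0.  The convex distance d_τ is minorized by its
   tangent plane for the linear term; for the quadratic term, a Hölder
   bound valid for 1 ≤ p ≤ 2 gives d_τ² ≤ Σ_m w_m h_τ(e_m)² with
   w_m = h_τ(f_m)^{p−2} d_τ(Z)^{2−p}, and h_τ(e)² is capped by a touching
   quadratic of curvature 4 (its maximal second derivative).  The resulting
   separable quadratic majorizer is minimized exactly, one small Laplacian
   system per dimension, guaranteeing monotone descent.  A safeguard
   (step-halving toward the previous iterate) absorbs the floating-point
   floors needed at τ = 0 for p < 2; a genuine loss increase by an exact
   majorizer raises an internal-consistency error.

   Because every smoothed distance of a collapsed configuration is exactly
   equal, refitting disparities against *smoothed* distances would make
   collapse a global minimum.  Disparities are therefore always fit against
   the exact distances: refreshed once per positive-τ level (so each
   level's majorization phase is provably monotone at fixed τ and fixed
   disparities), with full alternation at the final τ = 0 level, where both
   the disparity update and the configuration update provably decrease the
   true penalized loss.  Inner loops stop at relative decrease < 1e−6 or at
   an iteration budget (500 at the exact level, 100 during warm-up levels).

3. **Multistart.**  Per expert: seeded i.i.d. uniform [−1, 1] random starts
   (the dissimilarities are first rescaled by their median off-diagonal
   entry, a rank-preserving normalization that puts starts and τ ladder on
   one scale), plus two deterministic starts that count against the same
   budget — classical scaling (Torgerson double centering) and a warm start
   from the expert's own unconstrained (λ = 0) solution, which the
   penalized descent then pulls toward the constraint.  Start seeds are
   nested (`SeedSequence(seed, spawn_key=(expert, start))`), so the start
   set for n is a superset of that for n−1 and best-of-n is non-increasing
   by construction.  Among converged starts the solution with the lowest
   exact stress-1 is selected (ties: lower penalized loss, then order).
   With few experts this selection is visibly bimodal on the Germany
   excerpt: the first respondent's best compromise basin is reached from
   only ~2% of random starts, so the reported mean stress varies between
   ≈ 0.085 and ≈ 0.115 across seed batches — an honest property of
   multistart selection on a three-expert panel.

Dimensionality scans share information across q: the best (q−1)-solution
padded with a zero column enters the q-candidate set both as-is (its stress
is unchanged by padding, making per-expert stress non-increasing in q by
construction) and refined by a τ = 0 descent.

The engine covers 1 ≤ p ≤ 2 (the Hölder majorizer's validity range); the
distance kernels themselves support any p ≥ 1 and the dominance sentinel.

## Ideology correlation

Only city-block fits are admitted to the dimension-interpretation stage: a
Euclidean configuration can be rotated without changing stress, so its
dimension-wise correlations are not identified.  For each expert and each
dimension, Kendall's tau-b (tie-corrected; 1–20 integer scales tie often)
is computed between party coordinates and ideology ratings, two-sided.
p-values: exact enumeration of the n! permutation null for n ≤ 8, the
tie-adjusted normal approximation otherwise; a collapsed (constant) axis
yields an undefined tau, recorded as NaN and never significant.  Following
the reporting convention this replicates, per-expert flags at p < .05 are
*not* corrected for multiple testing across experts or dimensions — a
deliberate caveat, not an oversight.  Under a null (coordinate-independent)
ideology the per-dimension flag rate measures ≈ 0.048 over 500 replicates.

Power at 10 parties is bounded by the same axis indeterminacy noted below
for coordinate recovery: roughly one synthetic panel in eight yields
near-perfect fits whose axes are ~45° mixtures of the latent axes, which
halves each dimension's correlation with an axis-aligned ideology
(tau ≈ 0.45, p just above .05 at n = 10).  With ideology an exact monotone
function of latent dimension 1, 93–95% of experts still show at least one
significant dimension; at the generator's default alignment of 0.8 the
rate is 86–88%.

## Synthetic generator

`SyntheticSpec` defaults mirror the survey's inclusion rule and the shape
of the bundled Germany excerpt: 10 parties, 8 policies, 7 experts (minima
5/7/7, whose product is the 245-dimension floor), latent dimension 2,
city-block latent metric, party coordinates N(0, party_scale²) with
party_scale = 1.  Per-expert heterogeneity is coordinate jitter with sd
0.1 · party_scale.  Policies load 80% on one latent dimension (round-robin
assignment, alternating signs) so separable city-block structure survives
the mapping; each policy column is affinely mapped onto [1, 20] from its
noiseless range, then pre-discretization noise (sd 0.5 grid steps) is
added and values are rounded half-away-from-zero and clipped — so the
stated noise is in grid units, as a rater would experience it.  Ideology is
0.8 · (latent dimension 1) + 0.2 · noise, rescaled to 1–20 integers;
alignment 0 gives an exactly null ideology for type-I checks.  Everything
is a deterministic function of the seed.

What the generator does *not* emulate: expert response styles, sympathy
bias, missing data, country-specific policy menus, or correlated policy
loadings.  Passing recovery tests therefore show that the pipeline
recovers the geometry it assumes when that geometry is present — not that
real expert panels satisfy those assumptions.

The ratings are linear policy projections of the latent coordinates and are
therefore metric-free; the generating Minkowski metric materializes where
it does for real raters — in how policy differences are combined into one
dissimilarity judgment.  "Data generated under p" accordingly means profile
dissimilarities of the generated survey computed at p_in = latent_metric_p
(`judgment_dissimilarities`), the end-to-end counterpart of the noise-free
latent oracle distances (`latent_dissimilarities`); the rank correlation
between the two routes exceeds 0.8 at default noise.

Metric-recovery experiments use the ratings-level route, and the choice is
substantive, not cosmetic: on the *exact* latent distances of ten objects,
the λ = 100 weakly constrained 2-D nonmetric city-block fit is rank-flexible
enough to accommodate both an expert's Euclidean rank order and the averaged
constraint matrix almost perfectly, while Euclidean fits are rigid — so
city-block attains lower stress even on Euclidean-generated noise-free data
(verified to 30 starts; the winning solutions are non-degenerate).  The
discretization and rating noise of the survey route restores a symmetric
comparison, and it is the survey, not the latent oracle, that the method
sees in practice.  This flexibility asymmetry is worth knowing about when
interpreting city-block-versus-Euclidean stress comparisons on small object
sets.

Coordinate-level recovery (per-dimension |r| vs truth under the city-block
symmetry group: translation, axis permutation, reflection — no continuous
rotation) is tested at 13 parties: with 10 parties the 45 pair ranks leave
genuine axis indeterminacy (near-zero-stress solutions with mixed axes
exist), while 78 pairs pin the axes to |r| > 0.99.

## Problem sizes and tolerances

Replicate studies in the test suite use 20 synthetic surveys per condition
with 3–6 starts per expert (the deterministic classical and warm starts
plus a few random ones), sizes the generative-recovery experiments above
showed to be sufficient; the Germany analysis and the acceptance script use
the full 50-start protocol.  The multistart is vectorized across
(expert × start) rows, so the 50-start protocol on the bundled data runs in
seconds.
Numerical tie-breaks and degenerate inputs: all-equal dissimilarities yield
constant mean disparities flagged degenerate; near-constant fitted
disparities (relative spread < 1e−6) flag the fit as degenerate so a
collapsed "good" stress is never silent; all-zero distance matrices raise.
Engine tolerances (τ ladder, inner tolerance 1e−6, iteration budgets,
halving limit 20) are all exposed on `EngineSettings`.

## Known limitations

- The fitted-space engine is restricted to p ∈ [1, 2]; dominance-metric
  *fitting* (as opposed to distance evaluation and the isometry identity)
  is out of scope.
- Multistart selection by lowest stress has visible seed-to-seed variance
  on very small expert panels (see above).
- Stress-1 comparisons across metrics use the same normalization for both
  p; no allowance is made for the differing flexibility of city-block and
  Euclidean configurations at equal q.
- No missing-data support: the design this models is complete by
  construction.
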