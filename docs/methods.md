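# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the known limits of what the tests demonstrate.

## Interaction model

The link model is a binary gradient-boosted tree classifier (LightGBM)
for `P(pair interacts | traits)`. Feature rows concatenate all resource
traits, all consumer traits and both taxon groups; categoricals are
mapped to target-independent integer codes fixed at fit time and reused
verbatim at prediction time, so the all-pairs metanetwork prediction
cannot drift from the training schema (any mismatch is a hard error).

Default training parameters follow conventional boosted-regression-tree
practice in ecology: learning rate 0.01, tree depth 3 (8 leaves), bag
fraction 0.5, minimum 5 rows per leaf, up to 5,000 trees. The tree count
is selected by early-stopped 5-fold cross-validated binary deviance and
the model is then refit on all rows at that count; this is the `gbm.step`
convention and proved markedly more stable than a single validation
holdout at training sizes around 10³ rows. All of these are plain
configuration (`linkmodel.DEFAULT_PARAMS`) and can be overridden per
call.

Evaluation is 10-fold stratified cross-validation (plain k-fold when a
class is rarer than the fold count, e.g. leave-one-out); each row is
scored exactly once by a model that never saw it. Reported scores: AUC
(Mann–Whitney), PR-AUC (step/average-precision interpolation — linear
interpolation in PR space is biased), accuracy, Cohen's kappa and MCC at
the classification rule `score > τ`, reported for both τ = 0.4 and 0.5.
Threshold selection offers `fixed` (default 0.4), `max_kappa` and
`max_youden` over the grid {0.01, …, 0.99} with ties broken toward the
smallest threshold. Note that with the strict `>` rule, perfectly
separated scores {0.1, 0.9} are already perfectly classified at τ = 0.10.

## Niche geometry

Functional interaction niches are convex-hull volumes in an ordination of
the partner level's traits:

1. **Gower dissimilarity** over the declared trait subset: numeric
   traits contribute `|x−y| / range`, categoricals `1[x≠y]`, averaged
   unweighted. Constant numeric traits are dropped with a warning (their
   Gower term is undefined); an all-constant subset is an error.
2. **Square-root correction** then **PCoA** (double-centering +
   eigendecomposition). Axes with eigenvalues above `1e-10 x` the
   largest are retained, up to `m_max` (default 4); coordinates are
   scaled by the square root of each eigenvalue. If negative eigenvalue
   mass exceeds 5% of the total a warning is emitted. One `m` is fixed
   per trophic level so all hulls are measured in the same space.
3. **Hull volume** via Qhull; for m = 1 the range; degenerate inputs
   (fewer than m+1 points, affinely dependent) return 0.
4. **Standardization**: member hull / global hull of all species at that
   level. Member sets with `|members| ≤ m` are flagged degenerate and
   scored 0 rather than evaluated in a lower dimension — mixing hull
   dimensionalities would break comparability of the 0–1 scale. The
   standardized value is clipped at 1 (members ⊆ global guarantees ≤ 1
   up to float noise).

A species' **rewiring capacity** is the standardized FRic of its partners
in the *pruned binary* metanetwork (pruning precedes all niche
quantification; a probability-weighted variant is deliberately out of
scope). The global-hull denominator makes capacity 1 interpretable as
"partners span the full partner trait space" and gives the exact
dominance property *cell potential ≥ every local member's capacity*,
which the test suite checks without tolerance.

## Rewiring potential and mapping

Per cell and trophic level, the partner pool is the union of metanetwork
partner sets over the locally present focal-level species; partners are
*not* filtered by local occurrence (the niche is fundamental, not
realised) unless the `local_partners` sensitivity switch is set. Empty
communities yield NA — distinct from a community of species with no
functional spread, which yields 0 with a degeneracy flag.

Bivariate map classes are `3·(richness tercile − 1) + potential tercile`
with tercile breaks at quantiles of the non-NA cells and ties assigned to
the lower bin; NA in either variable propagates. With heavily tied
potentials (many cells exactly at 1) upper classes can be empty — a
consequence of the deterministic tie rule, not a bug.

## Additive model (GAM)

`potential ~ s(richness) + s(lon, lat)`, Gaussian family, identity link,
fitted by penalized least squares:

- richness smooth: cubic B-splines, basis size k = 10, interior knots at
  data quantiles, penalty = integrated squared second derivative
  (computed exactly by 3-point Gauss–Legendre per knot interval). Its
  null space is the linear functions, so infinite smoothing collapses the
  term to a straight line (edf → 1), which the noiseless-linear recovery
  test exploits.
- spatial smooth: unpenalized linear lon/lat terms plus 30 Gaussian
  radial basis functions at k-means knots with a ridge penalty; the
  kernel width is 1.5x the median nearest-neighbour knot spacing so the
  basis resolves structure down to the knot grid.
- both smooths carry sum-to-zero constraints over the training cells
  (the B-spline constraint absorbed by a null-space reparameterisation),
  so `fitted = intercept + f_rich + f_spatial` exactly and partial
  effects are centered.
- smoothing parameters: GCV on a 13 x 13 log-spaced grid (10⁻⁶–10¹²).
  When GCV ties across the grid (noiseless responses representable in a
  penalty null space) the smoothest fit within a 10⁻⁶ relative tolerance
  wins. Effective degrees of freedom per smooth are the block traces of
  the hat-matrix factor; smooth p-values are Wald approximations on the
  penalized coefficient blocks, reported without multiple-testing
  correction (two independent models, one per level).

Identity-link Gaussian is the default even though potential lies in
[0, 1]; the responses analysed here sit well inside the interval and the
additive decomposition is exact only on this scale. A beta/logit variant
was considered and left out of scope.

`saturation_richness` reports the first grid point whose mean curve comes
within 5% of the plateau, measured relative to the curve's total rise.
For recovering a generating half-saturation constant h (95% of the
asymptote at r = 19h) the robust route — used by the tests — is to fit
the saturating form to the whole partial-effect curve; a single-crossing
statistic inherits spline wiggle at the plateau, and even reference GAM
machinery (mgcv, which one test cross-checks against) shows the same
sub-0.2%-of-range non-monotonic wiggle and plateau-onset spread.

## Synthetic study system

The generator emulates a plant–hummingbird-style pollination system at
desk scale. Defaults (all in `SynthConfig`):

| parameter | default | meaning |
|---|---|---|
| n_resource, n_consumer | 60, 40 | species pool sizes |
| grid, cell_size | 20 x 20, 0.5° | occurrence grid |
| n_sites | 30 | sampled site networks |
| p_max | 0.9 | kernel ceiling |
| sigma_log_mean/sd | log 3, 0.8 | per-consumer tolerance σ_j (mm) |
| delta_cat | 0.5 | colour-mismatch penalty |
| p_detect | 0.7 | per-site detection of a feasible link |
| corolla log-mean/sd | log 15, 0.5 | resource matching trait (mm) |
| bill log-mean/sd | log 15, 0.2 | consumer matching trait (mm) |
| range radii | log-normal, medians 3.3° / 3.6° | disk ranges, resource/consumer |

Choices worth explaining:

- **σ spread (log-sd 0.8)** spans roughly an order of magnitude from
  specialists to generalists, which is what makes niche breadth a
  recoverable, tolerance-dominated quantity.
- **Corolla spread > bill spread** mirrors real communities, where
  corolla lengths vary far more than bill lengths; it also ensures σ_j,
  not bill position, dominates a consumer's partner count.
- **Range radii** are sized so a sampled site holds ≈15 resources x 12
  consumers — the typical richness of the site networks this system
  emulates. Sparser sites starve the model of per-consumer information
  and make breadth recovery unstable.
- **Detection 0.7** reflects the substantial incompleteness of real
  flower-visitation sampling.
- Sub-streams of the RNG are derived per stage from (seed, fixed
  offset), so identical configs are bit-reproducible and stages can be
  re-run independently.

What the generator does *not* emulate: phylogenetic trait correlation
(taxon groups are k-means clusters of trait space), abundance-dependent
detection, realistic biogeography (ranges are disks), or heterogeneous
sampling effort across sites. Passing recovery tests therefore shows the
pipeline preserves trait-matching structure under Bernoulli detection
noise — not that it is robust to structured observation bias in real
archives.

Imputation fills missing traits with the taxon-group mean (numeric) or
mode with lexicographic tie-break (categorical), global fallback, and
records a per-cell flag; phylogenetic ancestral-state imputation is out
of scope, with taxon group retained as the model's proxy predictor.

## Problem sizes and determinism

The reference study (60 x 40 species, 30 sites, 400 cells) runs the full
pipeline including 10-fold CV in ~15 s on one CPU; the test suite in
~1 min. Hull-ratio discreteness matters at these sizes: the 4-D hull of a
~90% subset of 40–60 points is geometrically bounded near ~0.93 of the
full hull, so saturation-to-maximum properties are asserted on larger
pools (150 x 100) where the effect vanishes. All tests and the acceptance
script are seeded; LightGBM runs single-threaded deterministic.
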