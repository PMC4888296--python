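# Methods

This note documents the models and procedures implemented in `exurban`, the
choices made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Morphological spatial pattern analysis

The classifier partitions the foreground of a binary raster with four rules:

1. **Core** — pixels surviving `edge_width` successive erosions, where an
   erosion removes any foreground pixel with at least one background pixel
   among its connectivity-neighbours (8-neighbour structural element by
   default).  Pixels outside the raster count as background, so foreground
   touching the map border erodes; this slightly inflates Edge at borders.
2. **Islet** — whole connected components that contain no core pixel.
3. **Boundary zone** — non-core pixels reachable from core by at most
   `edge_width` geodesic dilation steps within the foreground.  Boundary
   pixels adjacent to the unbounded background component (or on the raster
   border) are **Edge**; pixels adjacent only to an enclosed background hole
   are **Perforation**; enclosed-by-foreground boundary pixels default to
   Edge.  Background components are labelled with the complementary
   connectivity (4 for 8-connected foreground), the standard topology
   pairing that avoids paradoxes.
4. **Connectors** — remaining foreground components, classified by their
   *contacts*: maximal connected pixel subsets adjacent to the zone (core +
   boundary) of some core component, where core components are connected
   components of the *core* mask.  A connector touching ≥ 2 distinct core
   components is **Bridge**; ≥ 2 contacts with a single core component,
   **Loop**; exactly one contact, **Branch**.  A contact-free connector
   cannot occur (it would be an islet).

Parity with the GUIDOS reference tool is *not* claimed — GUIDOS has extra
sub-classes and option flags.  All downstream compactness metrics depend only
on the islet / non-islet split, which the four rules determine unambiguously
at edge width 1.  The implementation is verified against an independent
brute-force re-implementation of the same rules on every 4×4 grid (65,536
cases) and 1,000 random 12×12 grids.

One open corner: single-pixel appendages attached to Edge rather than Core
are classified Branch by rule 4; reference tools may differ here.

## Landscape metrics

Buffers use pixel-centre-in-circle membership (standard, reproducible,
cheap).  Cover proportions exclude nodata cells from numerator and
denominator.  Forest patches are 8-connected components whose buffer-clipped
area strictly exceeds 0.45 ha (at 30 m pixels: more than 5 pixels).
"Forest edge" is measured as interior forest/non-forest 4-adjacency length in
metres; the buffer clip line itself contributes nothing, making the measure a
pure pattern quantity unaffected by buffer size.  This is a defensible but
non-unique operationalisation; a length-vs-density ambiguity exists in the
source literature and results depending on forest edge should be read with
that in mind.

Moran's I uses row-standardised inverse-distance weights by default (a common
ecology default; any weight matrix can be supplied) and a two-sided
permutation test with the +1 correction, centred on the null expectation
−1/(n−1).

The compactness index is computed from pixel counts (identical to areas at
uniform pixel size) and is undefined — NaN, with the stop excluded downstream
— wherever a buffer contains no exurban pixel.

## Hierarchical count adjustment

Per species, counts follow the over-dispersed Poisson model with per-stop
intercepts and decade-scaled trends (`Year_t = (year − mid-study year)/10`,
keeping trends O(1)), a first-year-observer effect, and zero-mean Normal
random effects for route conditions, observer identity and record-level
over-dispersion.  Route effects vary by route × year by default (route
conditions change among years); a static per-route variant is available.
Priors are weakly informative: Normal(0, 10²) on the fixed effects,
half-Normal(0, 2) on the three scales — standard choices for log-rate models,
and configurable.

The sampler is an adaptive Metropolis-within-Gibbs scheme.  Blocks of
conditionally independent parameters are updated jointly with element-wise
accept/reject (valid because the likelihood factorises over records); scalar
parameters and the scales get random-walk updates on the natural or log
scale, with proposal scales tuned to ~44 % acceptance during warm-up and
frozen afterwards.  Two families of extra moves fix the slow directions of
this posterior:

* **group rescale** `(u, σ) → (cu, cσ)` per random-effect family — the
  ancillarity–sufficiency ("non-centred") update that breaks the usual
  scale/effect funnel;
* **translation moves** along every additive confounding direction — whole
  effect families against stop intercepts, route-year cells against the
  intercepts and trends of that route's stops, observer effects against the
  cells they surveyed, and the first-year effect against observers or cells
  whose records are all first-year.  These directions are likelihood-
  invariant, so only the priors enter the accept ratio; the battery is
  repeated with a mixture of proposal scales because the directions are
  nearly flat.

Convergence is monitored with the classical split Gelman–Rubin factor per
parameter; the pipeline reruns a species with doubled chains when max R̂
exceeds 1.1 ("run until converged").  In the replicated recovery experiment
(20 data sets at N = 40 stops, T = 4 years, 2 chains × 6,000 draws after
3,000 warm-up, thinned by 3) every fit reached max R̂ < 1.1 and the nominal
95 % intervals covered the generating first-year effect and all three scales
in 20/20 replicates.

"Adjusted count" is the posterior summary (mean by default, median by flag)
of `exp(β0_stop + β1_stop·Year_t + Route_it)` — observer, first-year and
over-dispersion effects zeroed.  Retaining the route effect treats it as part
of the stop's habitat context; this is the single most interpretation-
sensitive choice in the pipeline, and `include_route=False` gives the
stricter alternative.

## TITAN

Candidate change points are midpoints between consecutive distinct gradient
values leaving at least `min_split` (default 5) sites on each side; ties in
the gradient collapse to a single candidate.  IndVal for each side of each
candidate is standardised to a z score against `n_perm` (default 250)
permutations of the gradient across sites; the species' change point and
direction maximise z (an IndVal-maximising variant is available by flag).
The p-value compares the observed *maximum* IndVal over all candidates and
sides with the same maximum under each permutation (+1 correction) — using
the max statistic keeps the permutation test valid despite the scan's
selection step, and the type-I rate is confirmed at the nominal 5 % over 500
null species.  Bootstrap resampling of sites (default 250 replicates; the
most literal reading of "250 permutations … and diagnostic indices" — the
published method leaves n_boot open) yields purity (fraction agreeing with
the observed direction), reliability (fraction with IndVal p ≤ 0.05) and the
5–95 % change-point quantiles; resamples on which the scan is undefined are
redrawn and counted.  Community-level sum(z) profiles are computed as a
secondary diagnostic.

Change-point recovery at the study's gradient design (60 sites, steps planted
uniformly in [20, 80]) has median error below one candidate gap.  Per-species
random streams are keyed by (seed, species name), so results are independent
of the abundance table's column order.  Sites may be pooled across years
(default, matching how adjusted counts per stop × year feed the gradient) or
analysed per year.

## Loess screen and additive models

The loess screen is a tricube-weighted local polynomial regression (default
degree 2, span 0.75) whose nonlinearity report compares loess and linear
residual sums of squares through an approximate F statistic with the loess
operator trace as model degrees of freedom.  No significance gate is applied
— all species proceed to the threshold analysis; the screen is descriptive.

The additive models are Gaussian-identity penalized regressions: cubic
B-spline bases (dimension 10 per smooth; reduced to u−1 for predictors with
only u distinct values, e.g. patch counts) with curvature penalties, plus a
null-space shrinkage penalty per smooth (the "double penalty" device) so that
uninformative terms can shrink to zero effective degrees of freedom.  The
per-term smoothing weights minimise GCV with the standard γ = 1.4 inflation
of the effective-degrees-of-freedom cost, guarding against GCV's tendency to
undersmooth at finite n; optimisation is derivative-free from several starts.
Reported quantities: per-term edf (trace of the hat-matrix block), Wald-type
approximate p-values on the penalized coefficients (chi-square with edf
degrees of freedom; approximate, as all penalized-fit p-values are),
deviance explained (= 1 − RSS/TSS for Gaussian identity fits), GCV, and an
AIC using the penalized fit's total edf.  Survey year enters as an
unpenalized factor (a smooth does not apply).

Backward selection follows classical stepwise elimination with AIC ranking:
while the weakest term's p-value exceeds 0.05 it is dropped; once all terms
are significant, a term is still removed if that lowers AIC under the
two-AIC-unit model-equivalence convention (the simpler of two models within
2 units is preferred).  Strict AIC-descent-only selection
(`alpha_remove=None, parsimony=0`) is available and keeps AIC monotone along
the path.  The comparison table reports full and best-fitted models with
ΔAIC relative to the best model and flags p < 0.01 terms as key factors.  In
50 replicates at n = 400 with a strong smooth signal and one pure-noise
predictor, the noise predictor is eliminated in ≥ 90 % of replicates and the
signal is always retained.

## Synthetic data

The generator plants known truth at every level:

* **Stops** sit on a jittered grid spaced 2.3 km apart (buffers of
  neighbouring stops never overlap another stop's development), grouped into
  routes; about a fifth are protected (full forest, no development).
* **Development** around each unprotected stop is a set of units on a
  4-pixel spacing lattice inside a 900-m disc: single-pixel islets and solid
  3×3 blocks (which contain core).  The lattice spacing guarantees islets
  remain MSPA islets through all periods.  Per-stop unit counts and
  islet/block mixes are heterogeneous, with a minority of block-dominated
  "clustered" stops supplying the high-compactness tail.  Across the four
  survey periods a growing fraction of islets converts to blocks (infill)
  and new units appear, so the pooled compactness gradient rises from
  roughly 10 % to roughly 45 % with large between-stop spread while
  development roughly doubles — the observed qualitative trajectory of
  scattered development becoming contiguous and clumped.  Forest is a
  per-stop rectangle mosaic cleared progressively around development.
* **Counts** are drawn from the hierarchical model run forward, with a
  per-species response term in the linear predictor — a step or sigmoid in
  the stop's 1-km compactness at a known change point, with known direction
  and effect size.  The default community has 11 species: six "forest"
  species with step-up responses and five "edge" species with mixed
  responses.  Observer tenures are staggered (observers active in the first
  study year count as experienced), making the first-year effect
  identifiable; defaults: first-year effect −0.3, route and observer scales
  0.2, over-dispersion 0.15 on the log scale.

What passing tests show — and what they do not: the generator produces
landscapes whose islet/block decomposition is exact and counts that follow
the fitted model's own stochastic structure.  Real Landsat-derived maps have
classification error, spatially autocorrelated habitat, road-following
development and species whose responses are not clean steps; recovery under
the generator therefore validates the *machinery* (the estimators find the
truth their models assume), not the ecological conclusions of any real
analysis.

## Problem sizes and numerical choices

Desk-scale defaults keep a full run in minutes: the study-scale scenario uses
125 stops × 4 periods × 11 species on a ~900×980 raster; the pipeline's MCMC
default is 2 chains × 5,000 draws after 3,000 warm-up (thinned by 4), with
automatic doubling on non-convergence; TITAN uses 250 permutations and 250
bootstrap replicates; GCV optimisation clips log smoothing weights to
[−20, 25] to keep the exponentials finite.  Degenerate inputs are rejected
with named errors (constant gradients, single observers, rank-deficient
designs, buffers leaving the raster), never silently patched.

## Known limitations

* No GUIDOS bit-parity; no multi-class MSPA or distance-weighted cores.
* The sampler is tuned to this model family; very sparse species (many
  all-zero stops) mix slowly and rely on the rerun-longer loop.
* Smooth-term p-values ignore smoothing-parameter selection uncertainty and
  are mildly anti-conservative; key-factor flags use p < 0.01 partly for
  this reason.
* The forest-edge and adjusted-count definitions are defensible choices among
  several; both are flagged above and switchable where alternatives exist.
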